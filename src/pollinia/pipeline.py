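"""End-to-end orchestration: from records to estimates, metrics, and files.

The run proceeds in the order the estimators depend on each other:

1. tabulate pollen-pool (or maternal) genotype frequencies, round-robin by
   default;
2. per visitor taxon, run the selfing estimator chain and bootstrap it with
   the inserted pollinium as the resampling unit (B = 1000 by default);
3. compare taxa pairwise on the bootstrap replicates;
4. compute control-corrected pollinator effectiveness, effort-adjusted
   relative abundance, importance, and the self-incompatibility-controlled
   importance, with Monte-Carlo product CIs from replicate-wise combination;
5. export the per-maternal-genotype direct-selfing table for external
   display-size regressions.

Every random draw derives from ``RunConfig.rng_seed`` through named spawned
streams, so two runs over the same inputs are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .genotypes import (
    FrequencyTable,
    frequency_table_frame,
    naive_frequencies,
    round_robin_frequencies,
)
from .io import RunConfig, VisitRecord
from .metrics import (
    control_mean_rates,
    effectiveness,
    importance,
    relative_abundance,
    sicpi_insertions,
    sicpi_removals,
    summarize_behavior,
)
from .resampling import (
    BootstrapResult,
    StatisticUndefined,
    bootstrap,
    mc_product_ci,
    pairwise_bootstrap_test,
    permutation_test,
)
from .selfing import (
    CONTROL,
    PolliniumRecord,
    SelfingEstimate,
    estimate_selfing,
    per_genotype_sdp,
)

logger = logging.getLogger("pollinia")


@dataclass
class PipelineResult:
    """Everything one run produces, ready for writing or inspection."""

    selfing: dict  # taxon -> SelfingEstimate
    selfing_bootstraps: dict  # taxon -> BootstrapResult of S_mp
    comparisons: pd.DataFrame  # pairwise S_mp bootstrap tests
    importance_table: pd.DataFrame
    per_genotype_sdp: pd.DataFrame
    behavior: pd.DataFrame
    pe_permutations: pd.DataFrame
    frequencies: FrequencyTable
    manifest: dict


def _seed_streams(seed: int, names: Sequence[str]) -> dict:
    """Named, order-independent child seeds below 2**31."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(names))
    return {
        name: int(child.generate_state(1, dtype=np.uint32)[0] % (2**31))
        for name, child in zip(names, children)
    }


def _chain_statistic(freqs, taxon, weighting):
    """Statistic for bootstrapping S_mp over a combined visitor+control pool.

    Replicates that lose every visitor pollinium or breach a partition
    domain are dropped (and counted) rather than clamped: clamping inside
    the loop would shrink the replicate spread and bias the SE toward zero.
    """

    def stat(resample):
        visitor = [p for p in resample if not p.is_control]
        controls = [p for p in resample if p.is_control]
        if not visitor:
            raise StatisticUndefined("resample lost all visitor pollinia")
        try:
            est = estimate_selfing(
                visitor, controls, freqs, taxon, policy="error", weighting=weighting
            )
        except ValueError as exc:
            raise StatisticUndefined(str(exc)) from None
        return est.S_mp

    return stat


def _resample_records(pollinia: list, unit: str) -> list:
    """Resampling units: individual pollinia or per-inflorescence arrays."""
    if unit == "pollinium":
        return [[p] for p in pollinia]
    arrays: dict = {}
    for p in pollinia:
        arrays.setdefault(p.visit_id or p.pollinium_id, []).append(p)
    return list(arrays.values())


def _flatten(arrays: list) -> list:
    return [p for arr in arrays for p in arr]


def _match_B(result: BootstrapResult, B: int, seed: int) -> np.ndarray:
    """Pad a deficient replicate vector back to B by resampling survivors.

    Needed when domain-violating replicates were dropped but the replicate-
    wise combination requires equal lengths.
    """
    est = result.estimates
    if est.size == B:
        return est
    rng = np.random.default_rng(seed)
    return est[rng.integers(0, est.size, size=B)]


def run_pipeline(
    visits: Sequence[VisitRecord],
    pollinia: Sequence[PolliniumRecord],
    config: Optional[RunConfig] = None,
) -> PipelineResult:
    """Run the full estimation pipeline over validated records."""
    config = config or RunConfig()
    visits = list(visits)
    pollinia = list(pollinia)

    control_visits = [v for v in visits if v.is_control]
    visitor_visits = [v for v in visits if not v.is_control]
    control_pollinia = [p for p in pollinia if p.is_control]
    visitor_pollinia = [p for p in pollinia if not p.is_control]
    taxa = sorted({p.taxon for p in visitor_pollinia})
    if not taxa:
        raise ValueError("no genotyped visitor pollinia: nothing to estimate")
    if not control_visits:
        logger.warning(
            "no control records: proceeding under a zero-contamination assumption"
        )

    stream_names = (
        ["freqs"]
        + [f"selfing:{t}" for t in taxa]
        + [f"pad:{t}" for t in taxa]
        + [f"pe:{t}" for t in taxa]
        + ["abundance", "pairwise", "permutation"]
    )
    seeds = _seed_streams(config.rng_seed, stream_names)

    # 1. pollen-pool genotype frequencies
    if config.freq_basis == "pollen_pool":
        pool = [p.pollinium_genotype for p in pollinia]
    else:
        pool = list({p.maternal_genotype.sample_id: p.maternal_genotype for p in pollinia}.values())
    freq_fn = round_robin_frequencies if config.freq_method == "round_robin" else naive_frequencies
    try:
        freqs = freq_fn(pool, basis=config.freq_basis)
    except ValueError:
        logger.warning("falling back to naive frequencies (single-locus data)")
        freqs = naive_frequencies(pool, basis=config.freq_basis)

    # 2. selfing estimator chain + bootstrap, per taxon
    selfing: dict = {}
    boots: dict = {}
    for taxon in taxa:
        mine = [p for p in visitor_pollinia if p.taxon == taxon]
        est = estimate_selfing(
            mine, control_pollinia, freqs, taxon,
            policy=config.clamp_policy, weighting=config.alpha_weighting,
        )
        combined = mine + control_pollinia
        if len(combined) >= 2:
            arrays = _resample_records(combined, config.resample_unit)
            stat = _chain_statistic(freqs, taxon, config.alpha_weighting)
            boot = bootstrap(
                arrays,
                lambda resample: stat(_flatten(resample)),
                B=config.n_bootstrap,
                seed=seeds[f"selfing:{taxon}"],
            )
            est.se_S_mp = boot.se
            est.ci_S_mp = (boot.ci_low, boot.ci_high)
            est.n_dropped_replicates = boot.n_dropped
            boots[taxon] = boot
        selfing[taxon] = est
        logger.info(
            "taxon %s: n=%d S_d=%.3f alpha_dT=%.3f alpha_dp=%.3f r_p=%.3f "
            "t_dT=%.3f t_dc=%.3f S_dp=%.3f S_mp=%.3f (se=%s, dropped=%d)",
            taxon, est.n_pollinia, est.S_d, est.alpha_dT, est.alpha_dp,
            est.r_p, est.t_dT, est.t_dc, est.S_dp, est.S_mp,
            f"{est.se_S_mp:.3f}" if est.se_S_mp is not None else "NA",
            est.n_dropped_replicates,
        )

    # 3. pairwise bootstrap comparisons of S_mp
    comp_rows = []
    pair_seed = seeds["pairwise"]
    for i, a in enumerate(taxa):
        for b in taxa[i + 1:]:
            if a in boots and b in boots:
                ra, rb = boots[a], boots[b]
                B = min(ra.estimates.size, rb.estimates.size)
                # trim to a common length if drops made them unequal
                ta = BootstrapResult.from_estimates(ra.estimates[:B], B=B)
                tb = BootstrapResult.from_estimates(rb.estimates[:B], B=B)
                test = pairwise_bootstrap_test(ta, tb, seed=pair_seed)
                pair_seed += 1
                comp_rows.append(
                    {
                        "taxon_a": a,
                        "taxon_b": b,
                        "quantity": "S_mp",
                        "proportion_positive": test.proportion_positive,
                        "significant": test.significant,
                    }
                )
    comparisons = pd.DataFrame(comp_rows)

    # 4. effectiveness, abundance, importance, SICPI
    cm = control_mean_rates(control_visits)
    per_visit_pe, per_taxon_pe = effectiveness(visitor_visits, cm)
    abundance = relative_abundance(visitor_visits, config.sampling_effort_ratio)
    si = config.self_incompatibility
    B = config.n_bootstrap

    abundance_boots: dict = {}
    visit_arrays = list(visitor_visits)
    for taxon in sorted({v.taxon for v in visitor_visits}):
        abundance_boots[taxon] = bootstrap(
            visit_arrays,
            lambda vs, t=taxon: relative_abundance(vs, config.sampling_effort_ratio).get(t, 0.0),
            B=B,
            seed=seeds["abundance"],
        )

    imp_rows = []
    for taxon in sorted({v.taxon for v in visitor_visits}):
        rows_t = per_visit_pe[per_visit_pe["taxon"] == taxon]
        pe_f = float(rows_t["PE_female"].mean())
        pe_m = float(rows_t["PE_male"].mean())
        ab = abundance[taxon]
        pi_f = importance(pe_f, ab)
        pi_m = importance(pe_m, ab)
        s_mp = selfing[taxon].S_mp if taxon in selfing else 0.0
        sic_f = sicpi_insertions(pi_f, s_mp, si)
        sic_m = sicpi_removals(pi_m, pi_f, s_mp, si)

        taxon_visits = [v for v in visitor_visits if v.taxon == taxon]
        cis: dict = {}
        if len(taxon_visits) >= 2:
            pe_boot_f = bootstrap(
                taxon_visits,
                lambda vs: float(effectiveness(vs, cm)[0]["PE_female"].mean()),
                B=B,
                seed=seeds[f"pe:{taxon}"],
            )
            pe_boot_m = bootstrap(
                taxon_visits,
                lambda vs: float(effectiveness(vs, cm)[0]["PE_male"].mean()),
                B=B,
                seed=seeds[f"pe:{taxon}"] + 1,
            )
            ab_est = _match_B(abundance_boots[taxon], B, seeds[f"pad:{taxon}"])
            ab_boot = BootstrapResult.from_estimates(ab_est, B=B)
            pi_boot_f = mc_product_ci([pe_boot_f, ab_boot])
            pi_boot_m = mc_product_ci([pe_boot_m, ab_boot])
            cis["PE_female"] = (pe_boot_f.ci_low, pe_boot_f.ci_high)
            cis["PE_male"] = (pe_boot_m.ci_low, pe_boot_m.ci_high)
            cis["PI_female"] = (pi_boot_f.ci_low, pi_boot_f.ci_high)
            cis["PI_male"] = (pi_boot_m.ci_low, pi_boot_m.ci_high)
            if taxon in boots:
                s_est = _match_B(boots[taxon], B, seeds[f"pad:{taxon}"] + 1)
                s_boot = BootstrapResult.from_estimates(s_est, B=B)
                sic_boot_f = mc_product_ci(
                    [pi_boot_f, s_boot],
                    combiner=lambda pi, s: pi * (1.0 - np.clip(s, 0, 1) * si),
                )
                sic_boot_m = mc_product_ci(
                    [pi_boot_m, pi_boot_f, s_boot],
                    combiner=lambda pim, pif, s: np.maximum(
                        pim - pif * np.clip(s, 0, 1) * si, 0.0
                    ),
                )
                cis["SICPI_female"] = (sic_boot_f.ci_low, sic_boot_f.ci_high)
                cis["SICPI_male"] = (sic_boot_m.ci_low, sic_boot_m.ci_high)

        imp_rows.append(
            {
                "taxon": taxon,
                "relative_abundance": ab,
                "S_mp": s_mp,
                "SI": si,
                "PE_female": pe_f,
                "PE_male": pe_m,
                "PI_female": pi_f,
                "PI_male": pi_m,
                "SICPI_female": sic_f,
                "SICPI_male": sic_m.value,
                "SICPI_male_clamped": sic_m.clamped,
                **{
                    f"{k}_ci_{side}": v[i]
                    for k, v in cis.items()
                    for i, side in enumerate(("low", "high"))
                },
            }
        )
    importance_table = pd.DataFrame(imp_rows)

    # 5. PE permutation tests between taxa
    perm_rows = []
    perm_seed = seeds["permutation"]
    pe_taxa = sorted(per_visit_pe["taxon"].unique())
    for func in ("PE_female", "PE_male"):
        if len(pe_taxa) > 2:
            p = permutation_test(
                per_visit_pe[func].to_numpy(),
                per_visit_pe["taxon"].to_numpy(),
                B=config.n_permutation,
                seed=perm_seed,
            )
            perm_seed += 1
            perm_rows.append(
                {"function": func, "taxon_a": "all", "taxon_b": "all", "p_value": p}
            )
        for i, a in enumerate(pe_taxa):
            for b in pe_taxa[i + 1:]:
                sub = per_visit_pe[per_visit_pe["taxon"].isin([a, b])]
                p = permutation_test(
                    sub[func].to_numpy(),
                    sub["taxon"].to_numpy(),
                    B=config.n_permutation,
                    seed=perm_seed,
                )
                perm_seed += 1
                perm_rows.append(
                    {"function": func, "taxon_a": a, "taxon_b": b, "p_value": p}
                )
    pe_permutations = pd.DataFrame(perm_rows)

    behavior = summarize_behavior(visitor_visits)
    per_genotype = per_genotype_sdp(pollinia, visits, policy=config.clamp_policy)

    n_unclassifiable = len(pollinia) - len(
        [p for p in pollinia if _has_shared_locus(p)]
    )
    manifest = {
        "package": "pollinia",
        "version": __version__,
        "config": config.as_dict(),
        "n_visits": len(visitor_visits),
        "n_controls": len(control_visits),
        "n_pollinia": len(visitor_pollinia),
        "n_control_pollinia": len(control_pollinia),
        "n_unclassifiable_pollinia": n_unclassifiable,
        "taxa": taxa,
    }
    return PipelineResult(
        selfing=selfing,
        selfing_bootstraps=boots,
        comparisons=comparisons,
        importance_table=importance_table,
        per_genotype_sdp=per_genotype,
        behavior=behavior,
        pe_permutations=pe_permutations,
        frequencies=freqs,
        manifest=manifest,
    )


def _has_shared_locus(p: PolliniumRecord) -> bool:
    m, g = p.maternal_genotype, p.pollinium_genotype
    return any(
        m.call(l) is not None and g.call(l) is not None for l in m.loci
    )


def selfing_frame(result: PipelineResult) -> pd.DataFrame:
    return pd.DataFrame([e.as_dict() for e in result.selfing.values()])


def write_results(result: PipelineResult, outdir, sep: str = ",") -> dict:
    """Write every result table plus a YAML run manifest; returns the paths."""
    import yaml

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    float_fmt = "%.17g"  # full double precision: numeric round-trips are exact
    paths = {}

    tables = {
        "selfing.csv": selfing_frame(result),
        "importance.csv": result.importance_table,
        "per_genotype_sdp.csv": result.per_genotype_sdp,
        "behavior.csv": result.behavior,
        "comparisons.csv": result.comparisons,
        "pe_permutations.csv": result.pe_permutations,
        "frequencies.csv": frequency_table_frame(result.frequencies),
    }
    for name, df in tables.items():
        path = outdir / name
        df.to_csv(path, sep=sep, index=False, float_format=float_fmt)
        paths[name] = str(path)

    manifest_path = outdir / "manifest.yaml"
    with open(manifest_path, "w") as fh:
        yaml.safe_dump(result.manifest, fh, sort_keys=True)
    paths["manifest.yaml"] = str(manifest_path)
    return paths


def read_results(outdir, sep: str = ",") -> dict:
    """Read back the delimited result tables written by :func:`write_results`."""
    outdir = Path(outdir)
    out = {}
    for path in sorted(outdir.glob("*.csv")):
        # exact float round-trip: files are written at full double precision
        out[path.name] = pd.read_csv(path, sep=sep, float_precision="round_trip")
    return out
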