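"""Self-pollination rate estimators for insect-inserted pollinia.

A pollinium is a coherent packet of pollen from one donor flower, so its
grains share a single diploid parental genotype: genotyping an inserted
pollinium reads out its donor. Comparing that genotype to the maternal
stem's genotype classifies each insertion as self or outcross (the *direct*
estimate, S_d). Two corrections follow:

* chance matches — with few microsatellite loci an outcross donor can share
  the maternal multilocus genotype, so apparent selfing overstates true
  selfing. The erroneous-assignment probability alpha is computed from
  pollen-pool genotype frequencies, and a method-of-moments step
  ``S_m = (S_d - alpha) / (1 - alpha)`` removes the bias;
* bag contamination — insects occasionally push pollinia through exclusion
  bags before the observed visit, so control (bagged, unvisited)
  inflorescences contribute a background that is partitioned out of both
  alpha and the outcrossing rate before correction.

All rates live on [0, 1]; sampling noise can push the partitioned
quantities outside that range, handled by an explicit clamp-or-error policy.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Optional, Sequence

from .genotypes import FrequencyTable, MultilocusGenotype, genotype_match_probability

logger = logging.getLogger("pollinia")

#: Taxon label reserved for bagged, unvisited control inflorescences.
CONTROL = "CONTROL"


@dataclass(frozen=True)
class PolliniumRecord:
    """One inserted pollinium: maternal genotype, pollinium genotype, taxon."""

    pollinium_id: str
    maternal_genotype: MultilocusGenotype
    pollinium_genotype: MultilocusGenotype
    taxon: str
    visit_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.taxon:
            raise ValueError("taxon must be nonempty")

    @property
    def is_control(self) -> bool:
        return self.taxon == CONTROL


class UnclassifiablePolliniumError(ValueError):
    """Maternal and pollinium genotypes share no co-genotyped locus."""


def classify_pollinium(record: PolliniumRecord) -> str:
    """Classify one insertion as ``"self"`` or ``"outcross"``.

    Self iff the unordered diploid genotypes are identical at every locus
    genotyped in both the maternal stem and the pollinium; any allele
    difference at any shared locus means outcross. Loci missing in either
    genotype are excluded from the comparison.
    """
    m, p = record.maternal_genotype, record.pollinium_genotype
    shared = [
        l
        for l in m.loci
        if m.call(l) is not None and p.call(l) is not None
    ]
    if not shared:
        raise UnclassifiablePolliniumError(
            f"pollinium {record.pollinium_id!r}: no co-genotyped locus"
        )
    return "self" if all(m.call(l) == p.call(l) for l in shared) else "outcross"


def _classifiable(pollinia: Iterable[PolliniumRecord]) -> list[PolliniumRecord]:
    kept = []
    for p in pollinia:
        try:
            classify_pollinium(p)
        except UnclassifiablePolliniumError:
            logger.warning(
                "pollinium %r excluded: no co-genotyped locus", p.pollinium_id
            )
            continue
        kept.append(p)
    return kept


def direct_selfing_rate(
    pollinia: Sequence[PolliniumRecord], group_by: str = "taxon"
) -> dict:
    """Observed self fraction S_d per group (taxon or maternal genotype).

    Returns ``{group: (S_d, n_classifiable)}``; the outcrossing rate is
    ``1 - S_d`` by construction. Groups with no classifiable pollinium are
    omitted with a warning.
    """
    if group_by not in ("taxon", "maternal_genotype"):
        raise ValueError(f"group_by must be 'taxon' or 'maternal_genotype', got {group_by!r}")
    groups: dict = defaultdict(list)
    for p in pollinia:
        key = p.taxon if group_by == "taxon" else p.maternal_genotype.sample_id
        groups[key].append(p)
    out = {}
    for key, members in groups.items():
        usable = _classifiable(members)
        if not usable:
            warnings.warn(f"group {key!r} has no classifiable pollinium; omitted")
            continue
        n_self = sum(classify_pollinium(p) == "self" for p in usable)
        out[key] = (n_self / len(usable), len(usable))
    return out


def alpha_direct(
    pollinia: Sequence[PolliniumRecord],
    freqs: FrequencyTable,
    weighting: str = "pollinium",
) -> float:
    """Erroneous-assignment probability alpha for a pollinium collection.

    alpha = sum over distinct inserted-pollinium multilocus genotypes i of
    w_i * P(match i), where P(match i) multiplies the pollen-pool diploid
    genotype frequencies across i's genotyped loci. With
    ``weighting="pollinium"`` each genotyped pollinium counts once; with
    ``"inflorescence"`` each visited inflorescence counts once (its pollinia
    share the weight equally).
    """
    if not pollinia:
        raise ValueError("empty pollinium collection")
    if weighting not in ("pollinium", "inflorescence"):
        raise ValueError(f"unknown weighting {weighting!r}")
    weights: Counter = Counter()
    genotypes: dict = {}
    if weighting == "pollinium":
        for p in pollinia:
            key = p.pollinium_genotype.signature(p.pollinium_genotype.loci)
            weights[key] += 1.0
            genotypes[key] = p.pollinium_genotype
    else:
        by_visit: dict = defaultdict(list)
        for p in pollinia:
            by_visit[p.visit_id if p.visit_id is not None else p.pollinium_id].append(p)
        for members in by_visit.values():
            share = 1.0 / len(members)
            for p in members:
                key = p.pollinium_genotype.signature(p.pollinium_genotype.loci)
                weights[key] += share
                genotypes[key] = p.pollinium_genotype
    total = sum(weights.values())
    return sum(
        (w / total) * genotype_match_probability(freqs, genotypes[key])
        for key, w in weights.items()
    )


class PartitionedRate(NamedTuple):
    """A control-partitioned rate plus whether it was clamped into [0, 1]."""

    value: float
    clamped: bool


def _partition(total: float, control: float, r_p: float, policy: str) -> PartitionedRate:
    if not 0.0 < r_p <= 1.0:
        raise ValueError(f"r_p must be in (0, 1], got {r_p}")
    if policy not in ("clamp", "error"):
        raise ValueError(f"unknown policy {policy!r}")
    raw = (total - (1.0 - r_p) * control) / r_p
    if 0.0 <= raw <= 1.0:
        return PartitionedRate(raw, False)
    if policy == "error":
        raise ValueError(
            f"partitioned rate {raw:.4f} outside [0, 1]: the domain condition "
            f"total > control * (1 - r_p) is violated (total={total}, "
            f"control={control}, r_p={r_p})"
        )
    logger.warning(
        "partitioned rate %.4f clamped into [0, 1] (total=%s, control=%s, r_p=%s)",
        raw, total, control, r_p,
    )
    return PartitionedRate(min(1.0, max(0.0, raw)), True)


def partition_alpha(
    alpha_dT: float, alpha_dc: float, r_p: float, policy: str = "clamp"
) -> PartitionedRate:
    """Visitor-attributable alpha: (alpha_dT - (1 - r_p) * alpha_dc) / r_p.

    ``alpha_dT`` is alpha over all insertions (visitor plus through-bag),
    ``alpha_dc`` over control insertions only, and ``r_p`` the proportion of
    insertions attributed to the visitor taxon. At ``r_p = 1`` this is the
    identity.
    """
    return _partition(alpha_dT, alpha_dc, r_p, policy)


def visitor_selfing_direct(
    t_dT: float, t_dc: float, r_p: float, policy: str = "clamp"
) -> PartitionedRate:
    """Visitor-attributable direct selfing: 1 - partitioned outcrossing.

    ``t_dT`` is the total direct-outcrossing rate over all insertions,
    ``t_dc`` the control outcrossing rate; the partitioned visitor
    outcrossing rate is converted back to a selfing rate.
    """
    t = _partition(t_dT, t_dc, r_p, policy)
    return PartitionedRate(1.0 - t.value, t.clamped)


def mom_selfing(S_dp: float, alpha_dp: float) -> PartitionedRate:
    """Method-of-moments selfing rate: (S_dp - alpha_dp) / (1 - alpha_dp).

    An outcross pollinium is misclassified as self with probability alpha,
    so the observed self fraction is S + (1 - S) * alpha; inverting gives
    the corrected rate. alpha = 1 carries no information and is an error.
    Results outside [0, 1] (sampling noise) are clamped and flagged.
    """
    if not 0.0 <= alpha_dp <= 1.0:
        raise ValueError(f"alpha_dp must be in [0, 1], got {alpha_dp}")
    if alpha_dp == 1.0:
        raise ValueError("alpha_dp = 1: chance matches explain any observation")
    raw = (S_dp - alpha_dp) / (1.0 - alpha_dp)
    if 0.0 <= raw <= 1.0:
        return PartitionedRate(raw, False)
    return PartitionedRate(min(1.0, max(0.0, raw)), True)


@dataclass
class SelfingEstimate:
    """The full estimator chain for one visitor taxon."""

    taxon: str
    n_pollinia: int
    S_d: float
    alpha_dT: float
    alpha_dc: float
    alpha_dp: float
    r_p: float
    t_dT: float
    t_dc: float
    S_dp: float
    S_mp: float
    clamped: bool = False
    se_S_mp: Optional[float] = None
    ci_S_mp: Optional[tuple] = None
    n_dropped_replicates: int = 0

    def as_dict(self) -> dict:
        d = {
            "taxon": self.taxon,
            "n_pollinia": self.n_pollinia,
            "S_d": self.S_d,
            "alpha_dT": self.alpha_dT,
            "alpha_dc": self.alpha_dc,
            "alpha_dp": self.alpha_dp,
            "r_p": self.r_p,
            "t_dT": self.t_dT,
            "t_dc": self.t_dc,
            "S_dp": self.S_dp,
            "S_mp": self.S_mp,
            "se_S_mp": self.se_S_mp,
            "ci_S_mp_low": self.ci_S_mp[0] if self.ci_S_mp else None,
            "ci_S_mp_high": self.ci_S_mp[1] if self.ci_S_mp else None,
            "clamped": self.clamped,
            "n_dropped_replicates": self.n_dropped_replicates,
        }
        return d


def estimate_selfing(
    taxon_pollinia: Sequence[PolliniumRecord],
    control_pollinia: Sequence[PolliniumRecord],
    freqs: FrequencyTable,
    taxon: str,
    policy: str = "clamp",
    weighting: str = "pollinium",
) -> SelfingEstimate:
    """Run the estimator chain for one visitor taxon.

    The "total" pool is the taxon's visitor-inserted pollinia plus all
    through-bag control insertions; r_p is the visitor share of that pool.
    With no controls, r_p = 1 and every partition reduces to the identity,
    i.e. S_dp = 1 - t_dT.
    """
    visitor = _classifiable(taxon_pollinia)
    controls = _classifiable(control_pollinia)
    if not visitor:
        raise ValueError(f"taxon {taxon!r}: no classifiable genotyped pollinium")
    combined = list(visitor) + list(controls)
    r_p = len(visitor) / len(combined)

    n_self_total = sum(classify_pollinium(p) == "self" for p in combined)
    S_dT = n_self_total / len(combined)
    t_dT = 1.0 - S_dT
    S_d_visitor = sum(classify_pollinium(p) == "self" for p in visitor) / len(visitor)
    if controls:
        t_dc = 1.0 - sum(classify_pollinium(p) == "self" for p in controls) / len(controls)
        alpha_dc = alpha_direct(controls, freqs, weighting)
    else:
        t_dc = 0.0
        alpha_dc = 0.0

    alpha_dT = alpha_direct(combined, freqs, weighting)
    a = partition_alpha(alpha_dT, alpha_dc, r_p, policy)
    s = visitor_selfing_direct(t_dT, t_dc, r_p, policy)
    m = mom_selfing(s.value, a.value)

    return SelfingEstimate(
        taxon=taxon,
        n_pollinia=len(visitor),
        S_d=S_d_visitor,
        alpha_dT=alpha_dT,
        alpha_dc=alpha_dc,
        alpha_dp=a.value,
        r_p=r_p,
        t_dT=t_dT,
        t_dc=t_dc,
        S_dp=s.value,
        S_mp=m.value,
        clamped=a.clamped or s.clamped or m.clamped,
    )


def per_genotype_sdp(
    pollinia: Sequence[PolliniumRecord],
    visits: Optional[Sequence] = None,
    policy: str = "clamp",
):
    """Direct selfing rate per maternal genotype x taxon, with display sizes.

    The outcrossing rate t_dT is pooled across all inflorescences sharing a
    maternal genotype (per taxon); control insertions on bagged
    inflorescences of the same genotype partition out the through-bag
    background. Inflorescence and stem sizes are averaged across the distinct
    visited inflorescences of each genotype. The table feeds external
    display-size regressions and is exported as-is.
    """
    import math

    import pandas as pd

    visitor = [p for p in _classifiable(pollinia) if not p.is_control]
    controls_by_genotype: dict = defaultdict(list)
    for p in _classifiable(pollinia):
        if p.is_control:
            controls_by_genotype[p.maternal_genotype.sample_id].append(p)

    sizes: dict = {}
    if visits is not None:
        for v in visits:
            sizes[v.visit_id] = (v.inflorescence_size, v.stem_size)

    groups: dict = defaultdict(list)
    for p in visitor:
        groups[(p.maternal_genotype.sample_id, p.taxon)].append(p)

    rows = []
    for (genotype_id, taxon), members in sorted(groups.items()):
        controls = controls_by_genotype.get(genotype_id, [])
        combined = members + controls
        r_p = len(members) / len(combined)
        t_dT = 1.0 - sum(classify_pollinium(p) == "self" for p in combined) / len(combined)
        if controls:
            t_dc = 1.0 - sum(classify_pollinium(p) == "self" for p in controls) / len(controls)
        else:
            t_dc = 0.0
        s = visitor_selfing_direct(t_dT, t_dc, r_p, policy)
        visit_ids = {p.visit_id for p in members if p.visit_id is not None}
        infl = [sizes[v][0] for v in visit_ids if v in sizes]
        stem = [sizes[v][1] for v in visit_ids if v in sizes]
        rows.append(
            {
                "maternal_genotype": genotype_id,
                "taxon": taxon,
                "n_pollinia": len(members),
                "S_dp": s.value,
                "clamped": s.clamped,
                "mean_inflorescence_size": sum(infl) / len(infl) if infl else math.nan,
                "mean_stem_size": sum(stem) / len(stem) if stem else math.nan,
            }
        )
    return pd.DataFrame(rows)
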