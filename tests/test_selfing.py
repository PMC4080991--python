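"""Self/outcross classification and the selfing-rate estimator chain."""

import numpy as np
import pytest

from pollinia import (
    CONTROL,
    SimulationConfig,
    TaxonSpec,
    UnclassifiablePolliniumError,
    alpha_direct,
    classify_pollinium,
    direct_selfing_rate,
    estimate_selfing,
    mom_selfing,
    naive_frequencies,
    partition_alpha,
    per_genotype_sdp,
    simulate_study,
    visitor_selfing_direct,
)

from conftest import mlg, pollinium, visit


class TestClassification:
    def test_identical_genotypes_are_self(self):
        g = mlg("m", "1/2", "3/4", "5/5", "6/7")
        p = mlg("p", "1/2", "3/4", "5/5", "6/7")
        assert classify_pollinium(pollinium("x", g, p)) == "self"

    def test_any_allele_difference_is_outcross(self):
        g = mlg("m", "1/2", "3/4", "5/5", "6/7")
        p = mlg("p", "1/2", "3/4", "5/5", "6/8")
        assert classify_pollinium(pollinium("x", g, p)) == "outcross"

    def test_missing_loci_excluded_from_comparison(self):
        g = mlg("m", "1/2", "3/4", "5/5", "6/7")
        p = mlg("p", "1/2", "3/4", "-", "-")
        assert classify_pollinium(pollinium("x", g, p)) == "self"

    def test_no_shared_locus_unclassifiable(self):
        g = mlg("m", "1/2", "-")
        p = mlg("p", "-", "3/4")
        with pytest.raises(UnclassifiablePolliniumError):
            classify_pollinium(pollinium("x", g, p))


class TestDirectSelfingRate:
    def test_counting(self):
        m = mlg("m", "1/1")
        records = [pollinium(f"p{i}", m, mlg(f"g{i}", "1/1")) for i in range(3)]
        records.append(pollinium("p3", m, mlg("g3", "1/2")))
        rates = direct_selfing_rate(records)
        assert rates["honeybee"] == (0.75, 4)

    def test_all_self_boundary(self):
        m = mlg("m", "1/1")
        records = [pollinium(f"p{i}", m, mlg(f"g{i}", "1/1")) for i in range(5)]
        assert direct_selfing_rate(records)["honeybee"] == (1.0, 5)

    def test_selfing_plus_outcrossing_is_one(self):
        m = mlg("m", "1/1")
        records = [
            pollinium(f"p{i}", m, mlg(f"g{i}", "1/1" if i % 3 else "1/2"))
            for i in range(9)
        ]
        s, n = direct_selfing_rate(records)["honeybee"]
        t = sum(classify_pollinium(p) == "outcross" for p in records) / n
        assert s + t == 1.0

    def test_grouped_totals_match_per_record_tally(self, rng):
        # 30-record fixture over two taxa and three maternal genotypes
        mothers = [mlg(f"m{i}", f"{i}/{i}", "1/2") for i in range(3)]
        records = []
        for i in range(30):
            m = mothers[i % 3]
            self_draw = rng.random() < 0.5
            pg = m if self_draw else mlg(f"d{i}", "8/9", "1/2")
            records.append(
                pollinium(f"p{i}", m, mlg(f"g{i}", *(
                    "/".join(pg.call(l)) for l in pg.loci)),
                    taxon="honeybee" if i % 2 else "bumblebee")
            )
        for group_by, key_fn in (
            ("taxon", lambda p: p.taxon),
            ("maternal_genotype", lambda p: p.maternal_genotype.sample_id),
        ):
            rates = direct_selfing_rate(records, group_by=group_by)
            for key, (s, n) in rates.items():
                members = [p for p in records if key_fn(p) == key]
                expected = sum(
                    classify_pollinium(p) == "self" for p in members
                ) / len(members)
                assert s == pytest.approx(expected)
                assert n == len(members)


class TestAlphaDirect:
    def test_single_genotype_product_rule(self):
        # per-locus genotype frequency 0.5 at both loci -> alpha = 0.25
        pool = [mlg("a", "1/1", "2/2"), mlg("b", "1/2", "2/3")]
        freqs = naive_frequencies(pool)
        rec = pollinium("p", mlg("m", "1/1", "2/2"), mlg("g", "1/1", "2/2"))
        assert alpha_direct([rec], freqs) == pytest.approx(0.25)

    def test_weighted_mean_of_match_probabilities(self):
        # genotype A matches with prob 0.25, genotype B with 0.04;
        # equal weights -> 0.145
        pool = (
            [mlg(f"a{i}", "1/1", "2/2") for i in range(5)]
            + [mlg(f"b{i}", "3/3", "4/4") for i in range(2)]
            + [mlg(f"c{i}", "5/6", "7/8") for i in range(3)]
        )
        freqs = naive_frequencies(pool)
        m = mlg("m", "9/9", "9/9")
        rec_a = pollinium("pa", m, mlg("ga", "1/1", "2/2"))
        rec_b = pollinium("pb", m, mlg("gb", "3/3", "4/4"))
        pa = 0.5 * 0.5
        pb = 0.2 * 0.2
        assert alpha_direct([rec_a], freqs) == pytest.approx(pa)
        assert alpha_direct([rec_b], freqs) == pytest.approx(pb)
        assert alpha_direct([rec_a, rec_b], freqs) == pytest.approx((pa + pb) / 2)

    def test_enumeration_oracle_on_six_genotype_pool(self):
        # alpha must equal the expected match fraction when donors are drawn
        # uniformly from the tabulated pool, computed by full enumeration
        pool = [
            mlg("d1", "1/1", "2/2", "3/3"),
            mlg("d2", "1/1", "2/2", "3/3"),
            mlg("d3", "1/2", "2/2", "3/4"),
            mlg("d4", "1/1", "2/3", "3/3"),
            mlg("d5", "4/4", "5/5", "6/6"),
            mlg("d6", "1/2", "2/3", "3/4"),
        ]
        freqs = naive_frequencies(pool)
        m = mlg("m", "0/0", "0/0", "0/0")
        records = [pollinium(f"p{i}", m, g) for i, g in enumerate(pool)]
        expected = 0.0
        for target in pool:  # weight 1/6 each
            matches = 1.0
            for locus in target.loci:
                matches *= (
                    sum(d.call(locus) == target.call(locus) for d in pool) / 6
                )
            expected += matches / 6
        assert alpha_direct(records, freqs) == pytest.approx(expected, abs=1e-12)

    def test_empty_collection_rejected(self):
        freqs = naive_frequencies([mlg("a", "1/1")])
        with pytest.raises(ValueError):
            alpha_direct([], freqs)


class TestPartitioning:
    def test_rp_one_is_identity(self):
        assert partition_alpha(0.3, 0.9, 1.0).value == pytest.approx(0.3)
        assert visitor_selfing_direct(0.46, 0.9, 1.0).value == pytest.approx(0.54)

    def test_direct_arithmetic(self):
        r = partition_alpha(0.3, 0.2, 0.5)
        assert r.value == pytest.approx(0.4)
        assert not r.clamped

    def test_eq3_arithmetic(self):
        # visitor outcrossing (0.4 - 0.5*0.8)/0.5 = 0 -> S_dp = 1
        r = visitor_selfing_direct(0.4, 0.8, 0.5)
        assert r.value == pytest.approx(1.0)

    def test_domain_violation_clamps_or_errors(self):
        clamped = partition_alpha(0.05, 0.2, 0.5, policy="clamp")
        assert clamped.value == 0.0
        assert clamped.clamped
        with pytest.raises(ValueError, match="domain condition"):
            partition_alpha(0.05, 0.2, 0.5, policy="error")

    def test_rp_zero_rejected(self):
        with pytest.raises(ValueError):
            partition_alpha(0.3, 0.2, 0.0)


class TestMomSelfing:
    def test_perfect_exclusion_limit(self):
        assert mom_selfing(0.7, 0.0).value == pytest.approx(0.7)

    def test_all_matches_explainable_by_chance(self):
        assert mom_selfing(0.3, 0.3).value == pytest.approx(0.0)

    def test_alpha_one_rejected(self):
        with pytest.raises(ValueError):
            mom_selfing(0.5, 1.0)

    def test_correction_never_raises_estimate(self):
        for s in np.linspace(0, 1, 11):
            for a in np.linspace(0, 0.9, 10):
                assert mom_selfing(s, a).value <= s + 1e-12

    def test_recovers_truth_under_weak_loci(self, rng):
        # 500 pollinia, true S = 0.5, deliberately weak loci (2 alleles/locus
        # at 2 loci -> alpha ~ 0.3): raw S_d overestimates, the corrected
        # estimate recovers 0.5 within 0.05
        config = SimulationConfig(
            seed=7,
            n_genets=40,
            n_loci=2,
            alleles_per_locus=2,
            allele_freq_spec="uniform",
            taxa=(TaxonSpec("bee", 300, 20.0, 0.1, 0.1, beta0=0.0, beta1=0.0),),
            control_count=0,
            contamination_rate=0.0,
            genotyping_missingness=0.0,
        )
        study = simulate_study(config)
        pol = [p for p in study.pollinia if not p.is_control]
        freqs = naive_frequencies([p.pollinium_genotype for p in pol])
        est = estimate_selfing(pol, [], freqs, "bee")
        true_s = study.truth.selfing_by_taxon["bee"]
        assert est.S_d > true_s + 0.05  # chance matches inflate raw S_d
        assert est.S_mp == pytest.approx(true_s, abs=0.05)


class TestPerGenotypeSdp:
    def test_single_self_pollinium_gives_one(self):
        m = mlg("m1", "1/2", "3/4")
        rec = pollinium("p0", m, mlg("g0", "1/2", "3/4"))
        table = per_genotype_sdp([rec])
        assert len(table) == 1
        assert table.iloc[0]["S_dp"] == 1.0

    def test_display_sizes_averaged_over_inflorescences(self):
        m = mlg("m1", "1/2", "3/4")
        recs = [
            pollinium("p0", m, m, visit_id="v1"),
            pollinium("p1", m, m, visit_id="v2"),
        ]
        visits = [
            visit("v1", infl=40, stem=100),
            visit("v2", infl=60, stem=200),
        ]
        table = per_genotype_sdp(recs, visits)
        assert table.iloc[0]["mean_inflorescence_size"] == 50.0
        assert table.iloc[0]["mean_stem_size"] == 150.0

    def test_reconciles_with_grouped_tally(self, rng):
        mothers = [mlg(f"m{i}", f"{i}/{i}", "1/2") for i in range(4)]
        records = []
        for i in range(40):
            m = mothers[i % 4]
            pg = m if rng.random() < 0.6 else mlg(f"d{i}", "8/9", "1/2")
            records.append(pollinium(f"p{i}", m, pg, taxon="bee"))
        table = per_genotype_sdp(records)
        grouped = direct_selfing_rate(records, group_by="maternal_genotype")
        # with no controls S_dp reduces to the grouped direct rate
        for _, row in table.iterrows():
            s, n = grouped[row["maternal_genotype"]]
            assert row["S_dp"] == pytest.approx(s)
            assert row["n_pollinia"] == n

    def test_missing_display_sizes_flagged(self):
        m = mlg("m1", "1/2")
        table = per_genotype_sdp([pollinium("p0", m, m)], visits=[])
        assert np.isnan(table.iloc[0]["mean_inflorescence_size"])


class TestEstimatorChain:
    def test_no_controls_reduces_to_direct(self):
        m = mlg("m", "1/1", "2/2")
        pol = [pollinium(f"p{i}", m, m) for i in range(3)] + [
            pollinium("p3", m, mlg("g", "1/2", "2/2"))
        ]
        freqs = naive_frequencies([p.pollinium_genotype for p in pol])
        est = estimate_selfing(pol, [], freqs, "honeybee")
        assert est.r_p == 1.0
        assert est.S_dp == pytest.approx(1.0 - est.t_dT)
        assert est.S_dp == pytest.approx(0.75)

    def test_strong_loci_alpha_near_zero_keeps_smp_close_to_sd(self, small_study):
        pol = [p for p in small_study.pollinia if p.taxon == "honeybee"]
        controls = [p for p in small_study.pollinia if p.is_control]
        freqs = naive_frequencies(
            [p.pollinium_genotype for p in small_study.pollinia]
        )
        est = estimate_selfing(pol, controls, freqs, "honeybee")
        assert est.alpha_dT < 0.05
        assert abs(est.S_mp - est.S_dp) < 0.05
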