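"""Frequency tables, clone collapsing, and match probabilities."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pollinia import (
    MultilocusGenotype,
    collapse_clones,
    genotype_match_probability,
    naive_frequencies,
    round_robin_frequencies,
)

from conftest import mlg


def random_genotypes(rng, n_samples, n_loci=3, n_alleles=4, missingness=0.0):
    loci = tuple(f"L{k + 1}" for k in range(n_loci))
    out = []
    for i in range(n_samples):
        calls = {}
        for locus in loci:
            if rng.random() < missingness:
                calls[locus] = None
            else:
                a, b = rng.integers(1, n_alleles + 1, size=2)
                calls[locus] = tuple(sorted((str(a), str(b))))
        if not any(v is not None for v in calls.values()):
            calls[loci[0]] = ("1", "1")
        out.append(MultilocusGenotype(f"s{i}", calls, loci=loci))
    return out


class TestCollapseClones:
    def test_full_clonality_collapses_to_one(self):
        samples = [mlg(f"s{i}", "1/2", "3/3") for i in range(5)]
        assert len(collapse_clones(samples)) == 1

    def test_all_distinct_untouched(self):
        samples = [mlg(f"s{i}", f"{i}/{i}", "1/2") for i in range(5)]
        assert len(collapse_clones(samples)) == 5

    def test_exclude_locus_merges_classes(self):
        # four samples distinct only at L3; leaving L3 out they share
        # (1/2, 3/4), so the class count drops from 4 to 1
        samples = [mlg(f"s{i}", "1/2", "3/4", f"{i}/{i}") for i in range(4)]
        assert len(collapse_clones(samples)) == 4
        assert len(collapse_clones(samples, exclude_locus="L3")) == 1

    def test_exclude_unknown_locus_raises(self):
        with pytest.raises(KeyError):
            collapse_clones([mlg("s0", "1/2")], exclude_locus="LX")

    def test_missing_calls_join_unique_compatible_class(self):
        complete = [mlg("a", "1/2", "3/4"), mlg("b", "5/6", "3/4")]
        joiner = mlg("c", "1/2", "-")  # unique match: class of 'a'
        ambiguous = mlg("d", "-", "3/4")  # compatible with both classes
        reps = collapse_clones(complete + [joiner, ambiguous])
        ids = {g.sample_id for g in reps}
        assert ids == {"a", "b", "d"}

    def test_empty_collection_rejected(self):
        with pytest.raises(ValueError):
            collapse_clones([])


class TestNaiveFrequencies:
    def test_direct_counts(self):
        table = naive_frequencies([mlg("a", "A/A"), mlg("b", "A/B")])
        assert table.allele_freqs["L1"] == {"A": 0.75, "B": 0.25}
        assert table.genotype_freqs["L1"] == {("A", "A"): 0.5, ("A", "B"): 0.5}

    def test_all_missing_locus_omitted(self):
        samples = [mlg("a", "1/1", "-"), mlg("b", "1/2", "-")]
        with pytest.warns(UserWarning, match="L2"):
            table = naive_frequencies(samples)
        assert "L2" not in table.genotype_freqs

    def test_matches_independent_tally_on_random_fixture(self, rng):
        samples = random_genotypes(rng, 50, missingness=0.1)
        table = naive_frequencies(samples)
        for locus in table.loci:
            calls = [g.call(locus) for g in samples if g.call(locus)]
            for geno, freq in table.genotype_freqs[locus].items():
                assert freq == pytest.approx(
                    sum(c == geno for c in calls) / len(calls)
                )
            alleles = [a for c in calls for a in c]
            for allele, freq in table.allele_freqs[locus].items():
                assert freq == pytest.approx(
                    alleles.count(allele) / len(alleles)
                )


class TestRoundRobin:
    def test_single_locus_rejected(self):
        with pytest.raises(ValueError, match="naive_frequencies"):
            round_robin_frequencies([mlg("a", "1/2"), mlg("b", "1/1")])

    def test_no_duplicates_equals_naive(self, rng):
        # round-robin only differs when genotypes collapse; quantified over
        # many random fixtures with unique multilocus genotypes
        for _ in range(20):
            samples = random_genotypes(rng, 12, n_loci=3, n_alleles=12)
            loci = samples[0].loci
            # collapsing is possible as soon as two samples agree on any
            # leave-one-out projection, so require full projection uniqueness
            projections = [
                [g.signature([l for l in loci if l != k]) for g in samples]
                for k in loci
            ]
            if any(len(set(p)) != len(p) for p in projections):
                continue
            rr = round_robin_frequencies(samples)
            nv = naive_frequencies(samples)
            for locus in nv.loci:
                assert rr.genotype_freqs[locus] == nv.genotype_freqs[locus]
                assert rr.allele_freqs[locus] == nv.allele_freqs[locus]

    def test_private_allele_counted_per_genet_not_per_ramet(self):
        # one genet contributes 10 ramets carrying private allele '9' at L1;
        # two other singleton genets carry 1/1. Per-ramet counting would give
        # the 9/9 genotype 10/12; per-genet counting gives 1/3.
        ramets = [mlg(f"r{i}", "9/9", "2/3") for i in range(10)]
        others = [mlg("x", "1/1", "4/5"), mlg("y", "1/1", "6/7")]
        table = round_robin_frequencies(ramets + others)
        assert table.genotype_freqs["L1"][("9", "9")] == pytest.approx(1 / 3)
        assert table.allele_freqs["L1"]["9"] == pytest.approx(2 / 6)
        naive = naive_frequencies(ramets + others)
        assert naive.genotype_freqs["L1"][("9", "9")] == pytest.approx(10 / 12)

    def test_degenerate_clonality(self):
        samples = [mlg(f"s{i}", "1/2", "3/4") for i in range(6)]
        table = round_robin_frequencies(samples)
        for locus in table.loci:
            assert len(table.genotype_freqs[locus]) == 1
            assert sum(table.genotype_freqs[locus].values()) == pytest.approx(1.0)


class TestMatchProbability:
    def test_product_rule(self):
        freqs = naive_frequencies(
            [mlg("a", "1/1", "2/2"), mlg("b", "1/2", "2/3")]
        )
        # each locus genotype has frequency 0.5 -> product 0.25
        assert genotype_match_probability(freqs, mlg("q", "1/1", "2/2")) == 0.25

    def test_unseen_genotype_zero_factor(self):
        freqs = naive_frequencies([mlg("a", "1/1", "2/2")])
        assert genotype_match_probability(freqs, mlg("q", "1/1", "9/9")) == 0.0

    def test_brute_force_oracle_on_toy_population(self):
        # enumerate every candidate donor, count genotype matches, divide
        pool = [
            mlg("p1", "1/1", "2/2"),
            mlg("p2", "1/1", "2/3"),
            mlg("p3", "1/2", "2/2"),
            mlg("p4", "1/1", "2/2"),
            mlg("p5", "3/3", "4/4"),
            mlg("p6", "1/1", "2/2"),
        ]
        freqs = naive_frequencies(pool)
        for target in pool:
            per_locus = 1.0
            for locus in target.loci:
                matches = sum(g.call(locus) == target.call(locus) for g in pool)
                per_locus *= matches / len(pool)
            assert genotype_match_probability(freqs, target) == pytest.approx(
                per_locus, abs=1e-12
            )

    def test_monotone_nonincreasing_in_loci(self, rng):
        pool = random_genotypes(rng, 30, n_loci=4, n_alleles=3)
        freqs = naive_frequencies(pool)
        for target in pool[:10]:
            probs = []
            for k in range(1, 5):
                sub = MultilocusGenotype(
                    target.sample_id,
                    {l: target.call(l) for l in target.loci[:k]},
                    loci=target.loci[:k],
                )
                probs.append(genotype_match_probability(freqs, sub))
            assert all(a >= b for a, b in zip(probs, probs[1:]))

    def test_fully_missing_genotype_rejected_at_construction(self):
        with pytest.raises(ValueError, match="at least one genotyped locus"):
            MultilocusGenotype("q", {"L1": None, "L2": None}, loci=("L1", "L2"))


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(min_value=2, max_value=30), st.integers(min_value=0, max_value=10_000))
def test_frequency_normalization_property(n, seed):
    """Allele and genotype frequencies each sum to 1 per locus."""
    rng = np.random.default_rng(seed)
    samples = random_genotypes(rng, n, n_loci=3, n_alleles=4, missingness=0.2)
    for table in (naive_frequencies(samples), round_robin_frequencies(samples)):
        for locus in table.loci:
            assert sum(table.allele_freqs[locus].values()) == pytest.approx(1.0, abs=1e-9)
            assert sum(table.genotype_freqs[locus].values()) == pytest.approx(1.0, abs=1e-9)
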