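"""Multilocus microsatellite genotypes and pollen-pool frequency tables.

Clonal herbs blur the line between "plant" and "stem": one genet may flower
through many ramets, so tabulating allele frequencies over stems deflates
genotypic diversity while tabulating over distinct genotypes inflates rare
alleles. The round-robin estimator threads between the two: for each locus it
identifies distinct multilocus genotypes over *the remaining* loci, then
counts the focal locus's alleles and diploid genotypes over one
representative per class.

All diploid genotypes are unordered allele pairs; missing calls are allowed
and excluded locus-wise.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Tuple

logger = logging.getLogger("pollinia")

#: An unordered diploid allele pair, stored sorted so A/B == B/A.
GenotypeCall = Tuple[str, str]


def make_call(allele1: object, allele2: object) -> GenotypeCall:
    """Normalize two allele labels into a sorted, unordered diploid call."""
    a, b = str(allele1), str(allele2)
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class MultilocusGenotype:
    """A diploid multilocus genotype with per-locus unordered allele pairs.

    Parameters
    ----------
    sample_id :
        Identifier of the stem or pollinium the genotype belongs to.
    calls :
        Mapping locus name -> unordered allele pair; a locus absent from the
        mapping (or mapped to ``None``) is a missing call.
    loci :
        Dataset-wide locus order. Defaults to the sorted keys of ``calls``.
    """

    sample_id: str
    calls: Mapping[str, Optional[GenotypeCall]] = field(default_factory=dict)
    loci: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        norm = {
            locus: (make_call(*pair) if pair is not None else None)
            for locus, pair in self.calls.items()
        }
        object.__setattr__(self, "calls", norm)
        if not self.loci:
            object.__setattr__(self, "loci", tuple(sorted(norm)))
        if not any(c is not None for c in norm.values()):
            raise ValueError(
                f"sample {self.sample_id!r}: at least one genotyped locus required"
            )

    def call(self, locus: str) -> Optional[GenotypeCall]:
        return self.calls.get(locus)

    @property
    def genotyped_loci(self) -> Tuple[str, ...]:
        return tuple(l for l in self.loci if self.calls.get(l) is not None)

    def signature(self, loci: Sequence[str]) -> Tuple[Optional[GenotypeCall], ...]:
        """Calls over ``loci`` in order, ``None`` marking missing ones."""
        return tuple(self.calls.get(l) for l in loci)

    def identical_at(self, other: "MultilocusGenotype", loci: Sequence[str]) -> bool:
        """True if the two genotypes agree at every locus co-genotyped in ``loci``."""
        shared = [
            l
            for l in loci
            if self.calls.get(l) is not None and other.calls.get(l) is not None
        ]
        if not shared:
            return False
        return all(self.calls[l] == other.calls[l] for l in shared)


@dataclass
class FrequencyTable:
    """Per-locus allele and unordered diploid-genotype frequencies.

    ``method`` is ``"naive"`` (straight counting over samples) or
    ``"round_robin"`` (counting over leave-one-locus-out genotype classes);
    ``basis`` records which pool was tabulated (maternal stems or inserted
    pollinia).
    """

    allele_freqs: dict  # locus -> {allele: frequency}
    genotype_freqs: dict  # locus -> {GenotypeCall: frequency}
    method: str = "naive"
    basis: str = "pollen_pool"

    def __post_init__(self) -> None:
        for locus, freqs in self.allele_freqs.items():
            total = sum(freqs.values())
            if freqs and abs(total - 1.0) > 1e-9:
                raise ValueError(f"allele frequencies at {locus} sum to {total}")
        for locus, freqs in self.genotype_freqs.items():
            total = sum(freqs.values())
            if freqs and abs(total - 1.0) > 1e-9:
                raise ValueError(f"genotype frequencies at {locus} sum to {total}")

    @property
    def loci(self) -> Tuple[str, ...]:
        return tuple(self.genotype_freqs)

    def genotype_frequency(self, locus: str, call: GenotypeCall) -> float:
        if locus not in self.genotype_freqs:
            raise KeyError(f"locus {locus!r} not in frequency table")
        return self.genotype_freqs[locus].get(make_call(*call), 0.0)


def _dataset_loci(genotypes: Sequence[MultilocusGenotype]) -> Tuple[str, ...]:
    loci: list[str] = []
    for g in genotypes:
        for l in g.loci:
            if l not in loci:
                loci.append(l)
    return tuple(loci)


def collapse_clones(
    genotypes: Sequence[MultilocusGenotype],
    exclude_locus: Optional[str] = None,
) -> list[MultilocusGenotype]:
    """Reduce a sample collection to one representative per distinct genotype.

    Classes are formed over all dataset loci except ``exclude_locus``.
    Samples fully genotyped at the retained loci define the classes; a sample
    with missing calls joins an existing class only when it is identical at
    every co-genotyped locus to exactly one class — ambiguity or no match
    makes it its own class. This is deliberately conservative: over-collapsing
    distinct genets would re-inflate rare-allele frequencies, the bias the
    round-robin estimator exists to avoid.
    """
    if not genotypes:
        raise ValueError("empty genotype collection")
    loci = _dataset_loci(genotypes)
    if exclude_locus is not None:
        if exclude_locus not in loci:
            raise KeyError(f"exclude_locus {exclude_locus!r} not in dataset loci {loci}")
        loci = tuple(l for l in loci if l != exclude_locus)
    if not loci:
        raise ValueError("no loci retained after exclusion")

    complete: dict[tuple, MultilocusGenotype] = {}
    incomplete: list[MultilocusGenotype] = []
    for g in genotypes:
        sig = g.signature(loci)
        if all(c is not None for c in sig):
            complete.setdefault(sig, g)
        elif any(c is not None for c in sig):
            incomplete.append(g)
        # samples with no calls at the retained loci carry no information here
        # and are dropped from the class list

    reps = list(complete.values())
    extra: list[MultilocusGenotype] = []
    for g in incomplete:
        matches = [r for r in reps if g.identical_at(r, loci)]
        if len(matches) == 1:
            continue  # absorbed into the unique compatible class
        extra.append(g)
    return reps + extra


def naive_frequencies(
    genotypes: Sequence[MultilocusGenotype],
    basis: str = "pollen_pool",
) -> FrequencyTable:
    """Tabulate allele and diploid-genotype frequencies over all samples.

    Missing calls are excluded locus-wise from the denominator; a locus with
    no genotyped sample is omitted with a warning.
    """
    if not genotypes:
        raise ValueError("empty genotype collection")
    loci = _dataset_loci(genotypes)
    allele_freqs: dict = {}
    genotype_freqs: dict = {}
    for locus in loci:
        calls = [g.call(locus) for g in genotypes if g.call(locus) is not None]
        if not calls:
            warnings.warn(f"locus {locus!r} has no genotyped samples; omitted")
            logger.warning("locus %r has no genotyped samples; omitted", locus)
            continue
        geno_counts = Counter(calls)
        allele_counts: Counter = Counter()
        for a, b in calls:
            allele_counts[a] += 1
            allele_counts[b] += 1
        n_geno = sum(geno_counts.values())
        n_alleles = sum(allele_counts.values())
        genotype_freqs[locus] = {g: c / n_geno for g, c in geno_counts.items()}
        allele_freqs[locus] = {a: c / n_alleles for a, c in allele_counts.items()}
    return FrequencyTable(allele_freqs, genotype_freqs, method="naive", basis=basis)


def round_robin_frequencies(
    genotypes: Sequence[MultilocusGenotype],
    basis: str = "pollen_pool",
) -> FrequencyTable:
    """Leave-one-locus-out frequency estimation for clonal populations.

    For each locus k, distinct-genotype classes are formed over all loci
    except k (``collapse_clones``) and locus-k frequencies tabulated over one
    representative per class, so a genet contributing many ramets counts once.
    Requires >= 2 loci; with a single locus there is nothing to leave out.
    """
    if not genotypes:
        raise ValueError("empty genotype collection")
    loci = _dataset_loci(genotypes)
    if len(loci) < 2:
        raise ValueError(
            "round-robin estimation requires >= 2 loci; use naive_frequencies"
        )
    allele_freqs: dict = {}
    genotype_freqs: dict = {}
    for locus in loci:
        reps = collapse_clones(genotypes, exclude_locus=locus)
        calls = [g.call(locus) for g in reps if g.call(locus) is not None]
        if not calls:
            warnings.warn(f"locus {locus!r} has no genotyped class representatives; omitted")
            continue
        geno_counts = Counter(calls)
        allele_counts: Counter = Counter()
        for a, b in calls:
            allele_counts[a] += 1
            allele_counts[b] += 1
        n_geno = sum(geno_counts.values())
        n_alleles = sum(allele_counts.values())
        genotype_freqs[locus] = {g: c / n_geno for g, c in geno_counts.items()}
        allele_freqs[locus] = {a: c / n_alleles for a, c in allele_counts.items()}
    return FrequencyTable(
        allele_freqs, genotype_freqs, method="round_robin", basis=basis
    )


def genotype_match_probability(
    freqs: FrequencyTable, mlg: MultilocusGenotype
) -> float:
    """Probability that a random pool member carries ``mlg``'s genotype.

    The product over the genotyped loci of the table's (counted, not
    Hardy-Weinberg) unordered diploid-genotype frequency; a genotype unseen
    in the pool at any locus drives the product to zero.
    """
    loci = mlg.genotyped_loci
    if not loci:
        raise ValueError(f"sample {mlg.sample_id!r} has no genotyped loci")
    prob = 1.0
    for locus in loci:
        prob *= freqs.genotype_frequency(locus, mlg.call(locus))  # type: ignore[arg-type]
    return prob


def frequency_table_frame(table: FrequencyTable):
    """Flatten a FrequencyTable into a long-format pandas DataFrame."""
    import pandas as pd

    rows = []
    for locus, freqs in table.allele_freqs.items():
        for allele, f in sorted(freqs.items()):
            rows.append((locus, "allele", allele, f, table.method, table.basis))
    for locus, freqs in table.genotype_freqs.items():
        for geno, f in sorted(freqs.items()):
            rows.append((locus, "genotype", "/".join(geno), f, table.method, table.basis))
    return pd.DataFrame(
        rows, columns=["locus", "kind", "label", "frequency", "method", "basis"]
    )
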