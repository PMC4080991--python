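import numpy as np
import pytest

from pollinia import (
    CONTROL,
    MultilocusGenotype,
    PolliniumRecord,
    VisitRecord,
)


def mlg(sample_id, *pairs, loci=None):
    """Build a MultilocusGenotype from 'a/b' strings; '-' marks missing."""
    if loci is None:
        loci = tuple(f"L{k + 1}" for k in range(len(pairs)))
    calls = {}
    for locus, pair in zip(loci, pairs):
        if pair in (None, "-"):
            calls[locus] = None
        else:
            a, b = pair.split("/")
            calls[locus] = (a, b) if a <= b else (b, a)
    return MultilocusGenotype(sample_id, calls, loci=tuple(loci))


def pollinium(pid, maternal, pollen, taxon="honeybee", visit_id=None):
    return PolliniumRecord(pid, maternal, pollen, taxon, visit_id)


def visit(visit_id="v1", taxon="honeybee", flowers=10, infl=50, stem=None,
          insertions=1, removals=2, period="diurnal", maternal=None):
    if stem is None:
        stem = 2 * infl
    return VisitRecord(
        visit_id=visit_id,
        taxon=taxon,
        flowers_visited=flowers,
        inflorescence_size=infl,
        stem_size=stem,
        insertions=insertions,
        removals=removals,
        period=period,
        maternal_genotype_id=maternal,
    )


def control_visit(visit_id="c1", infl=50, stem=None, insertions=0):
    if stem is None:
        stem = 2 * infl
    return VisitRecord(
        visit_id=visit_id,
        taxon=CONTROL,
        flowers_visited=0,
        inflorescence_size=infl,
        stem_size=stem,
        insertions=insertions,
        removals=0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_study():
    """A small but complete synthetic study shared across tests."""
    from pollinia import SimulationConfig, simulate_study

    return simulate_study(SimulationConfig(seed=42, control_count=30,
                                           contamination_rate=0.2))
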