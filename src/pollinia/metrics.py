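"""Pollinator effectiveness and importance indices.

Effectiveness (PE) is measured per focal-inflorescence flower per visit,
separately for female function (pollinium insertions) and male function
(pollinium removals), after subtracting the mean per-flower rate observed on
bagged control inflorescences; negative values are set to zero. Importance
(PI) weights a taxon's mean PE by its relative visit abundance, with
nocturnal visit counts scaled by the diurnal:nocturnal sampling-effort
ratio. Because the plant is strongly self-incompatible, a self-pollinium
insertion rarely sires seed: the self-incompatibility-controlled importance
(SICPI) discounts the selfed, incompatible fraction —

    SICPI_I = PI_I * (1 - S_mp * SI)          (insertions)
    SICPI_R = PI_R - PI_I * S_mp * SI         (removals)

where S_mp is the corrected selfing rate and SI the self-incompatibility
rate (1 minus the self-compatible fraction; default SI = 0.95 from a
conservative 5% self-compatibility).
"""

from __future__ import annotations

import logging
import warnings
from collections import defaultdict
from typing import Iterable, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

from .selfing import CONTROL

logger = logging.getLogger("pollinia")


class ControlMeans(NamedTuple):
    """Mean per-flower insertion and removal rates on bagged controls."""

    insertions_per_flower: float
    removals_per_flower: float


def control_mean_rates(controls: Sequence) -> ControlMeans:
    """Average per-flower insertion/removal rates over control inflorescences.

    Empty control sets return zeros with a prominent warning — the pipeline
    then proceeds under a zero-contamination assumption.
    """
    usable = [c for c in controls if c.inflorescence_size > 0]
    if not usable:
        warnings.warn(
            "no control inflorescences: assuming zero through-bag contamination"
        )
        logger.warning("no control inflorescences: contamination assumed zero")
        return ControlMeans(0.0, 0.0)
    ins = [c.insertions / c.inflorescence_size for c in usable]
    rem = [c.removals / c.inflorescence_size for c in usable]
    return ControlMeans(float(np.mean(ins)), float(np.mean(rem)))


def effectiveness(
    visits: Sequence, control_means: ControlMeans
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-visit and per-taxon pollinator effectiveness, both functions.

    PE for a visit is max(0, count / inflorescence_size - control mean) for
    each function; the per-taxon value is the mean over that taxon's visits.
    Returns ``(per_visit, per_taxon)`` frames.
    """
    rows = []
    for v in visits:
        if v.taxon == CONTROL:
            continue
        if v.inflorescence_size <= 0:
            raise ValueError(f"visit {v.visit_id!r}: inflorescence_size must be > 0")
        pe_i = max(0.0, v.insertions / v.inflorescence_size - control_means.insertions_per_flower)
        pe_r = max(0.0, v.removals / v.inflorescence_size - control_means.removals_per_flower)
        rows.append({"visit_id": v.visit_id, "taxon": v.taxon, "PE_female": pe_i, "PE_male": pe_r})
    per_visit = pd.DataFrame(rows)
    if per_visit.empty:
        raise ValueError("no non-control visits")
    per_taxon = (
        per_visit.groupby("taxon")[["PE_female", "PE_male"]].mean().reset_index()
    )
    return per_visit, per_taxon


def relative_abundance(
    visits: Sequence, effort_ratio: float = 1.0
) -> dict[str, float]:
    """Visit share per taxon, with nocturnal counts effort-adjusted.

    ``effort_ratio`` is diurnal observation hours divided by nocturnal
    observation hours; nocturnal visit counts are multiplied by it before
    normalization so that unequal watch time does not masquerade as rarity.
    """
    if effort_ratio <= 0:
        raise ValueError(f"effort_ratio must be > 0, got {effort_ratio}")
    weights: dict[str, float] = defaultdict(float)
    for v in visits:
        if v.taxon == CONTROL:
            continue
        w = effort_ratio if getattr(v, "period", "diurnal") == "nocturnal" else 1.0
        weights[v.taxon] += w
    total = sum(weights.values())
    if total == 0:
        raise ValueError("no non-control visits")
    return {taxon: w / total for taxon, w in sorted(weights.items())}


def abundance_from_counts(
    counts: dict[str, float],
    nocturnal_taxa: Iterable[str] = (),
    effort_ratio: float = 1.0,
) -> dict[str, float]:
    """Relative abundance from per-taxon visit totals (tabulated data)."""
    if effort_ratio <= 0:
        raise ValueError(f"effort_ratio must be > 0, got {effort_ratio}")
    nocturnal = set(nocturnal_taxa)
    weights = {
        t: c * (effort_ratio if t in nocturnal else 1.0) for t, c in counts.items()
    }
    total = sum(weights.values())
    if total <= 0:
        raise ValueError("visit counts sum to zero")
    return {t: w / total for t, w in sorted(weights.items())}


def importance(pe: float, abundance: float) -> float:
    """Pollinator importance: effectiveness times relative abundance."""
    if pe < 0 or abundance < 0:
        raise ValueError("PE and abundance must be nonnegative")
    return pe * abundance


class ClampedMetric(NamedTuple):
    value: float
    clamped: bool


def sicpi_insertions(pi_female: float, s_mp: float, si: float) -> float:
    """Self-incompatibility-controlled importance for insertions.

    ``PI_I * (1 - S_mp * SI)``: only the fraction of insertions not lost to
    selfing-into-incompatibility counts toward female reproductive success.
    Reduces to PI when S_mp = 0 (no selfing) or SI = 0 (full compatibility).
    """
    _check_unit("S_mp", s_mp)
    _check_unit("SI", si)
    return pi_female * (1.0 - s_mp * si)


def sicpi_removals(
    pi_male: float, pi_female: float, s_mp: float, si: float
) -> ClampedMetric:
    """Self-incompatibility-controlled importance for removals.

    ``PI_R - PI_I * S_mp * SI``: removals spent on incompatible self
    insertions are discounted from male function (pollen discounting).
    Negative results (heavy discounting at small PI_R) clamp to 0 with a
    flag.
    """
    _check_unit("S_mp", s_mp)
    _check_unit("SI", si)
    if pi_male < 0 or pi_female < 0:
        raise ValueError("importance values must be nonnegative")
    raw = pi_male - pi_female * s_mp * si
    if raw < 0:
        logger.warning("SICPI_R %.4f clamped to 0", raw)
        return ClampedMetric(0.0, True)
    return ClampedMetric(raw, False)


def _check_unit(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must be in [0, 1], got {value}")


def summarize_behavior(visits: Sequence) -> pd.DataFrame:
    """Per-taxon mean +/- SE of flowers visited, insertions, and removals."""
    rows = [
        {
            "taxon": v.taxon,
            "flowers_visited": v.flowers_visited,
            "insertions": v.insertions,
            "removals": v.removals,
        }
        for v in visits
        if v.taxon != CONTROL
    ]
    if not rows:
        raise ValueError("no non-control visits")
    df = pd.DataFrame(rows)

    def _sem(x):
        return x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1 else np.nan

    out = df.groupby("taxon").agg(
        n=("flowers_visited", "size"),
        flowers_visited_mean=("flowers_visited", "mean"),
        flowers_visited_se=("flowers_visited", _sem),
        insertions_mean=("insertions", "mean"),
        insertions_se=("insertions", _sem),
        removals_mean=("removals", "mean"),
        removals_se=("removals", _sem),
    )
    return out.reset_index()


def compatible_insertions_per_inflorescence(
    mean_inflorescence_size: float,
    insertions_per_flower: float,
    selfing_rate: float,
) -> float:
    """Expected self-compatible (outcross) insertions on one inflorescence.

    flowers x insertions-per-flower x (1 - selfing rate): the pollen-
    limitation yardstick comparing compatible pollen receipt with observed
    fruit set.
    """
    if mean_inflorescence_size < 0 or insertions_per_flower < 0:
        raise ValueError("sizes and rates must be nonnegative")
    _check_unit("selfing_rate", selfing_rate)
    return mean_inflorescence_size * insertions_per_flower * (1.0 - selfing_rate)
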