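"""Resampling inference: bootstrap, pairwise bootstrap tests, permutations.

The uncertainty conventions used throughout the pipeline:

* statistics are bootstrapped with the inserted pollinium (or, optionally,
  the per-inflorescence pollinium array) as the resampling unit, B = 1000 by
  default, with-replacement at the original sample size;
* a bootstrap mean and SE are the mean and standard deviation of the
  replicates; the 95% CI is the 25th and 975th ranked replicate (for
  B = 1000), i.e. the 2.5% / 97.5% order statistics in general;
* two taxa differ significantly when more than 97.5% — or fewer than
  2.5% — of randomly paired replicate differences are positive (two-tailed);
* permutation p-values use the add-one Monte-Carlo estimator
  p = (1 + #{permuted >= observed}) / (B + 1), which cannot reach zero;
* variances of products of random variables (pollinator importance and its
  self-incompatibility-controlled variant) come from combining component
  bootstrap replicates replicate-wise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, NamedTuple, Optional, Sequence

import numpy as np


@dataclass
class BootstrapResult:
    """B replicate values of a statistic plus their summaries."""

    estimates: np.ndarray
    mean: float
    se: float
    ci_low: float
    ci_high: float
    B: int
    seed: Optional[int] = None
    n_dropped: int = 0

    @classmethod
    def from_estimates(
        cls,
        estimates: Sequence[float],
        B: int,
        seed: Optional[int] = None,
        n_dropped: int = 0,
    ) -> "BootstrapResult":
        est = np.asarray(estimates, dtype=float)
        if est.size == 0:
            raise ValueError("no surviving bootstrap replicates")
        lo, hi = _rank_ci(est)
        return cls(
            estimates=est,
            mean=float(est.mean()),
            se=float(est.std(ddof=0)),
            ci_low=lo,
            ci_high=hi,
            B=B,
            seed=seed,
            n_dropped=n_dropped,
        )

    def as_dict(self) -> dict:
        return {
            "mean": self.mean,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "B": self.B,
            "n_dropped": self.n_dropped,
        }


def _rank_ci(estimates: np.ndarray) -> tuple[float, float]:
    """25th/975th ranked values at B = 1000; same order statistics otherwise."""
    ranked = np.sort(estimates)
    b = ranked.size
    lo_idx = max(int(np.ceil(0.025 * b)) - 1, 0)
    hi_idx = min(int(np.floor(0.975 * b)) - 1, b - 1)
    return float(ranked[lo_idx]), float(ranked[hi_idx])


class StatisticUndefined(Exception):
    """Raised by a statistic when a resample falls outside its domain.

    Replicates raising this (e.g. a control-partition domain violation) are
    dropped and counted rather than clamped: clamping inside the resampling
    loop would shrink the spread and bias the SE toward zero.
    """


def bootstrap(
    records: Sequence,
    statistic: Callable[[list], float],
    B: int = 1000,
    seed: Optional[int] = None,
) -> BootstrapResult:
    """Bootstrap ``statistic`` over with-replacement resamples of ``records``.

    Each of the B resamples has the original size; replicates where the
    statistic raises :class:`StatisticUndefined` are excluded and counted in
    ``n_dropped``.
    """
    records = list(records)
    n = len(records)
    if n < 2:
        raise ValueError("bootstrap requires >= 2 records")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(B, n))
    estimates = []
    dropped = 0
    for b in range(B):
        resample = [records[i] for i in idx[b]]
        try:
            estimates.append(float(statistic(resample)))
        except StatisticUndefined:
            dropped += 1
    return BootstrapResult.from_estimates(estimates, B=B, seed=seed, n_dropped=dropped)


class PairwiseBootstrapTest(NamedTuple):
    proportion_positive: float
    n_positive: int
    significant: bool


def pairwise_bootstrap_test(
    a: BootstrapResult, b: BootstrapResult, seed: Optional[int] = None
) -> PairwiseBootstrapTest:
    """Two-tailed comparison of two bootstrap distributions.

    Draws B independently indexed replicate pairs (a_i - b_j) and counts the
    positive differences; the difference is significant when the count
    exceeds 0.975 * B or falls below 0.025 * B (at B = 1000: > 975 or < 25).
    Ties (difference exactly zero) count as not-greater. The two results are
    independent resamples of different record sets, so indices are drawn
    independently rather than aligned.
    """
    if a.estimates.size != b.estimates.size:
        raise ValueError(
            f"bootstrap sizes differ ({a.estimates.size} vs {b.estimates.size})"
        )
    B = a.estimates.size
    rng = np.random.default_rng(seed)
    i = rng.integers(0, B, size=B)
    j = rng.integers(0, B, size=B)
    diffs = a.estimates[i] - b.estimates[j]
    n_pos = int(np.count_nonzero(diffs > 0))
    significant = n_pos > 0.975 * B or n_pos < 0.025 * B
    return PairwiseBootstrapTest(n_pos / B, n_pos, significant)


def _two_sample_abs_mean_diff(values: np.ndarray, masks: np.ndarray) -> np.ndarray:
    """|mean(group0) - mean(group1)| for each row-wise permutation."""
    n0 = masks[0].sum()
    n1 = masks[1].sum()
    m0 = values @ masks[0] / n0
    m1 = values @ masks[1] / n1
    return np.abs(m0 - m1)


def permutation_test(
    values: Sequence[float],
    labels: Sequence,
    statistic: Optional[Callable[[np.ndarray, np.ndarray], float]] = None,
    B: int = 1000,
    seed: Optional[int] = None,
) -> float:
    """Label-permutation p-value for a group contrast on per-visit values.

    With two groups the default statistic is the absolute difference of
    group means; with k > 2 groups it is the visit-count-weighted variance
    of group means (an ANOVA-like contrast). p uses the add-one estimator
    (1 + #{permuted >= observed}) / (B + 1). Degenerate data (all values
    identical) give p = 1 automatically.

    A custom ``statistic`` receives ``(values, group_index_array)`` and must
    return a scalar with larger values meaning a stronger contrast.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if len(groups) < 2:
        raise ValueError("permutation test requires >= 2 groups")
    group_idx = np.searchsorted(groups, labels)
    counts = np.bincount(group_idx, minlength=len(groups))
    if (counts == 0).any():
        raise ValueError("every group must be nonempty")

    if statistic is not None:
        observed = statistic(values, group_idx)
        rng = np.random.default_rng(seed)
        exceed = 0
        for _ in range(B):
            perm = rng.permutation(group_idx)
            if statistic(values, perm) >= observed:
                exceed += 1
        return (1 + exceed) / (B + 1)

    # vectorized default statistics: permute labels by permuting values
    rng = np.random.default_rng(seed)
    n = values.size
    perm_values = np.empty((B, n))
    for b in range(B):
        perm_values[b] = values[rng.permutation(n)]

    if len(groups) == 2:
        mask0 = (group_idx == 0).astype(float)
        mask1 = (group_idx == 1).astype(float)
        observed = abs(values @ mask0 / counts[0] - values @ mask1 / counts[1])
        permuted = np.abs(
            perm_values @ mask0 / counts[0] - perm_values @ mask1 / counts[1]
        )
    else:
        masks = np.stack([(group_idx == g).astype(float) for g in range(len(groups))])
        w = counts / n

        def _between_var(mat: np.ndarray) -> np.ndarray:
            means = (mat @ masks.T) / counts  # (..., k)
            grand = mat.mean(axis=-1, keepdims=True)
            return ((means - grand) ** 2 @ w)

        observed = float(_between_var(values[None, :])[0])
        permuted = _between_var(perm_values)

    exceed = int(np.count_nonzero(permuted >= observed))
    return (1 + exceed) / (B + 1)


def mc_product_ci(
    components: Sequence[BootstrapResult],
    combiner: Callable[..., np.ndarray] = None,
    seed: Optional[int] = None,
) -> BootstrapResult:
    """Combine component bootstraps replicate-wise into a product-type CI.

    Replicate k of every component is passed to ``combiner`` (default: the
    elementwise product), producing B combined replicates whose ranked
    25th/975th values give the CI. All components must share B. ``seed`` is
    accepted for interface symmetry; the combination itself is deterministic.
    """
    if not components:
        raise ValueError("at least one component required")
    sizes = {c.estimates.size for c in components}
    if len(sizes) != 1:
        raise ValueError(f"component bootstrap sizes differ: {sorted(sizes)}")
    arrays = [c.estimates for c in components]
    if combiner is None:
        combined = np.prod(np.stack(arrays), axis=0)
    else:
        combined = np.asarray(combiner(*arrays), dtype=float)
    B = arrays[0].size
    if combined.shape != (B,):
        raise ValueError("combiner must return one value per replicate")
    return BootstrapResult.from_estimates(
        combined, B=B, seed=seed, n_dropped=sum(c.n_dropped for c in components)
    )
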