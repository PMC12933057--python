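"""Shared resampling and test utilities.

Label-permutation shuffle tests with 1st/99th-percentile flags, percentile
bootstrap, and chi-square goodness of fit.  All randomness flows through a
caller-supplied seed or :class:`numpy.random.Generator` so results are
reproducible and independent of call order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "ShuffleResult",
    "BootstrapResult",
    "shuffle_test",
    "bootstrap",
    "chi_square_gof",
]


def as_rng(seed) -> np.random.Generator:
    """Accept an int seed, a Generator, or None and return a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class ShuffleResult:
    """Outcome of a label-permutation test.

    ``flag`` is 'low' if the observed statistic falls below the 1st
    percentile of the null draws, 'high' if above the 99th, else 'within'.
    ``p_value`` is the two-sided permutation p with attained floor
    2/n_shuffles (an observation outside all draws cannot be claimed more
    significant than that).
    """

    observed: float
    null_draws: np.ndarray
    percentile: float
    flag: str
    p_value: float


@dataclass
class BootstrapResult:
    estimate: float
    se: float
    ci: tuple
    level: float
    replicates: np.ndarray = field(repr=False)


def shuffle_test(
    statistic: Callable,
    data,
    labels: Sequence,
    n_shuffles: int = 1000,
    seed=None,
) -> ShuffleResult:
    """Permutation null for ``statistic(data, labels)`` under label exchange.

    The observed statistic is compared with ``n_shuffles`` recomputations on
    permuted labels; flags follow the 1st/99th-percentile convention.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    rng = as_rng(seed)
    labels = np.asarray(labels)
    observed = float(statistic(data, labels))
    if not np.isfinite(observed):
        raise ValueError("observed statistic is not finite")
    null = np.empty(n_shuffles)
    for i in range(n_shuffles):
        null[i] = statistic(data, rng.permutation(labels))
    # order-statistic thresholds: under the null the observed value falls
    # outside with probability <= 1% per side (no interpolation liberality)
    lo = np.quantile(null, 0.01, method="lower")
    hi = np.quantile(null, 0.99, method="higher")
    if observed < lo:
        flag = "low"
    elif observed > hi:
        flag = "high"
    else:
        flag = "within"
    percentile = float(sps.percentileofscore(null, observed, kind="mean"))
    # two-sided permutation p with attained floor 2/n_shuffles
    n_ge = int(np.sum(null >= observed))
    n_le = int(np.sum(null <= observed))
    p = 2.0 * (min(n_ge, n_le) + 1) / (n_shuffles + 1)
    p = float(min(1.0, max(p, 2.0 / n_shuffles)))
    return ShuffleResult(observed, null, percentile, flag, p)


def bootstrap(
    statistic: Callable,
    sample,
    n_boot: int = 500,
    level: float = 0.95,
    seed=None,
) -> BootstrapResult:
    """Nonparametric bootstrap SE and percentile CI of ``statistic(sample)``."""
    sample = np.asarray(sample)
    n = sample.shape[0]
    if n < 2:
        raise ValueError("bootstrap needs a sample of size >= 2")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    rng = as_rng(seed)
    reps = np.empty(n_boot)
    for i in range(n_boot):
        reps[i] = statistic(sample[rng.integers(0, n, size=n)])
    alpha = 100 * (1 - level) / 2
    ci = tuple(np.percentile(reps, [alpha, 100 - alpha]))
    return BootstrapResult(
        estimate=float(statistic(sample)),
        se=float(np.std(reps, ddof=1)),
        ci=ci,
        level=level,
        replicates=reps,
    )


def chi_square_gof(counts, expected_props):
    """Chi-square goodness of fit of observed counts to expected proportions.

    Returns ``(statistic, p)`` with the upper-tail p on k-1 degrees of
    freedom. Expected counts must all be >= 1.
    """
    counts = np.asarray(counts, dtype=float)
    expected_props = np.asarray(expected_props, dtype=float)
    if counts.shape != expected_props.shape:
        raise ValueError("counts and expected_props must align")
    expected = expected_props / expected_props.sum() * counts.sum()
    if np.any(expected < 1):
        raise ValueError("expected counts must be >= 1")
    stat, p = sps.chisquare(counts, expected)
    return float(stat), float(p)
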