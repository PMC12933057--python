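"""Interspike-interval profiles, population PCA, and the bursting index.

Each unit's ISI histogram (1 ms bins over (0, 100] ms, normalized to a
probability vector) is decomposed by PCA across units; the bursting index of
a unit is its loading on PC1 minus its loading on PC3, which emphasizes the
peaked short-ISI shape characteristic of burst firing.  Component signs are
fixed so each PC is positive at the population's modal ISI bin (falling back
to the largest-magnitude element), making the index reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy import stats as sps
from sklearn.decomposition import PCA

__all__ = [
    "DEFAULT_BIN_EDGES_MS",
    "InsufficientSpikesError",
    "ISIPCAResult",
    "isi_histogram",
    "isi_pca",
    "bursting_index",
    "partial_correlation",
]

#: 1 ms linear bins over (0, 100] ms.
DEFAULT_BIN_EDGES_MS = np.arange(0.0, 101.0, 1.0)
MIN_ISIS = 100


class InsufficientSpikesError(ValueError):
    """Raised when a train has too few ISIs for a stable histogram."""


def isi_histogram(
    spike_times_s,
    bin_edges_ms: np.ndarray = DEFAULT_BIN_EDGES_MS,
    min_isis: int = MIN_ISIS,
) -> np.ndarray:
    """Probability histogram of consecutive ISIs; intervals past the last edge drop."""
    st = np.sort(np.asarray(spike_times_s, dtype=float))
    isis_ms = np.diff(st) * 1000.0
    if isis_ms.size < min_isis:
        raise InsufficientSpikesError(
            f"{isis_ms.size} ISIs < required {min_isis}: unit excluded"
        )
    counts, _ = np.histogram(isis_ms, bins=bin_edges_ms)
    total = counts.sum()
    if total == 0:
        raise InsufficientSpikesError("no ISIs inside the histogram range")
    return counts / total


@dataclass
class ISIPCAResult:
    components: np.ndarray  # (n_components, n_bins)
    loadings: np.ndarray  # (n_units, n_components)
    explained_variance_ratio: np.ndarray
    mean_profile: np.ndarray
    degenerate: bool = False


def isi_pca(profiles, n_components: int = 3) -> ISIPCAResult:
    """PCA of centered ISI probability vectors across units.

    Loadings are projections onto the components.  Sign convention: each
    component is flipped so its value at the population's modal ISI bin is
    positive (largest-|value| element positive when that is ~0).  A set of
    identical profiles is degenerate and flagged.
    """
    P = np.asarray(profiles, dtype=float)
    if P.ndim != 2 or P.shape[0] < 3:
        raise ValueError("need >= 3 units (rows) of ISI profiles")
    n_components = min(n_components, min(P.shape))
    mean_profile = P.mean(axis=0)
    degenerate = bool(np.allclose(P, mean_profile[None, :]))
    pca = PCA(n_components=n_components, svd_solver="full")
    loadings = pca.fit_transform(P)
    components = pca.components_.copy()
    modal_bin = int(np.argmax(mean_profile))
    for k in range(components.shape[0]):
        ref = components[k, modal_bin]
        if abs(ref) < 1e-12:
            ref = components[k, int(np.argmax(np.abs(components[k])))]
        if ref < 0:
            components[k] *= -1.0
            loadings[:, k] *= -1.0
    return ISIPCAResult(
        components=components,
        loadings=loadings,
        explained_variance_ratio=pca.explained_variance_ratio_,
        mean_profile=mean_profile,
        degenerate=degenerate,
    )


def bursting_index(loadings: np.ndarray) -> np.ndarray:
    """Per-unit bursting index: loading on PC1 minus loading on PC3."""
    L = np.atleast_2d(np.asarray(loadings, dtype=float))
    if L.shape[1] < 3:
        raise ValueError("need loadings on at least three components")
    out = L[:, 0] - L[:, 2]
    return out if out.size > 1 else float(out[0])


def partial_correlation(x, y, covariate) -> Tuple[float, float, bool]:
    """Pearson correlation of x and y after regressing out a covariate.

    Returns ``(r, p, plain_fallback)``; p uses a t distribution with n-3
    degrees of freedom.  A constant covariate falls back to the plain
    Pearson correlation (flagged).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    c = np.asarray(covariate, dtype=float)
    n = x.size
    if n < 10:
        raise ValueError("need n >= 10 observations")
    if not (y.size == n and c.size == n):
        raise ValueError("inputs must align")
    if np.ptp(c) == 0:
        r, p = sps.pearsonr(x, y)
        return float(r), float(p), True
    X = np.column_stack([np.ones(n), c])
    rx = x - X @ np.linalg.lstsq(X, x, rcond=None)[0]
    ry = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
    # perfect confounding: no residual variance left, no partial association
    if np.std(rx) <= 1e-10 * max(np.std(x), 1e-300) or np.std(ry) <= 1e-10 * max(
        np.std(y), 1e-300
    ):
        return 0.0, 1.0, False
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 3
    r_ = min(max(r, -0.9999999999), 0.9999999999)
    t = r_ * np.sqrt(df / (1.0 - r_**2))
    p = float(2.0 * sps.t.sf(abs(t), df))
    return r, p, False
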