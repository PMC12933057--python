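"""Multichannel spatiotemporal waveform analysis.

Action potentials recorded on a high-density probe appear on several
channels around the soma; the per-channel trough time traces the spike's
propagation.  This module extracts the soma-centered channel window
(five channels above and below by default), measures per-channel
trough/peak times relative to the soma trough, regresses trough time on
signed distance separately above and below the soma (the propagation
slopes, ms/um), and summarizes each cluster with outlier-trimmed mean
trajectories, an asymmetry index (distance of the slope pair from the
y = -x line), and bootstrap inference at the 95%/98% levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Tuple

import numpy as np

from .qc import WaveformTemplate, max_channel
from .stats import as_rng

__all__ = [
    "PropagationWindow",
    "PropagationProfile",
    "ClusterTrajectory",
    "BootstrapSlopes",
    "extract_window",
    "trough_peak_times",
    "unit_profile",
    "cluster_trajectory",
    "propagation_slopes",
    "asymmetry_index",
    "bootstrap_slope_tests",
    "compare_asymmetry",
]

AMPLITUDE_FLOOR_FRAC = 0.15


@dataclass
class PropagationWindow:
    """Soma-centered channel window; offsets positive above (shallower)."""

    voltages: np.ndarray  # samples x channels, ordered by offset ascending
    offsets_um: np.ndarray
    fs_hz: float
    soma_index: int
    truncated: bool


@dataclass
class PropagationProfile:
    """Per-unit trough/peak times (ms, relative to the soma trough)."""

    offsets_um: np.ndarray
    trough_times_ms: np.ndarray
    peak_times_ms: np.ndarray
    slope_above: float = np.nan
    slope_below: float = np.nan
    asymmetry: float = np.nan


@dataclass
class ClusterTrajectory:
    offsets_um: np.ndarray
    mean_ms: np.ndarray
    sem_ms: np.ndarray
    n_used: np.ndarray
    low_n: bool = False


@dataclass
class BootstrapSlopes:
    slope_above: float
    slope_below: float
    asymmetry: float
    se_above: float
    se_below: float
    se_asymmetry: float
    ci_below_95: Tuple[float, float]
    below_excludes_zero: bool
    replicates: np.ndarray = field(repr=False)
    degenerate: bool = False


def extract_window(template: WaveformTemplate, n_each_side: int = 5) -> PropagationWindow:
    """Soma channel plus up to ``n_each_side`` channels above and below.

    Truncates (and flags) at the probe edge.  Channels are returned in order
    of ascending signed offset (deepest/below first, soma at ``soma_index``).
    """
    soma, _ = max_channel(template)
    depths = template.channel_depths_um
    lo = max(0, soma - n_each_side)
    hi = min(template.n_channels, soma + n_each_side + 1)
    truncated = bool(lo > soma - n_each_side or hi < soma + n_each_side + 1)
    idx = np.arange(lo, hi)
    offsets = depths[soma] - depths[idx]  # positive above (shallower)
    order = np.argsort(offsets)
    return PropagationWindow(
        voltages=template.voltages[:, idx[order]],
        offsets_um=offsets[order],
        fs_hz=template.fs_hz,
        soma_index=int(np.argmin(np.abs(offsets[order]))),
        truncated=truncated,
    )


def trough_peak_times(
    window: PropagationWindow,
    amplitude_floor_frac: float = AMPLITUDE_FLOOR_FRAC,
) -> PropagationProfile:
    """Per-channel trough/peak times (ms) relative to the soma trough.

    Channels whose peak-to-trough amplitude falls below
    ``amplitude_floor_frac`` of the soma amplitude are reported as NaN.
    Waveforms are lightly smoothed (3-point triangular kernel) before the
    floor test and extremum search so template noise neither promotes a
    noise-dominated channel past the floor nor displaces an extremum; times
    are then refined by 3-point parabolic interpolation, resolving
    propagation delays below one sample.
    """

    def _refine(y, i):
        if 0 < i < y.size - 1:
            denom = y[i - 1] - 2 * y[i] + y[i + 1]
            if denom != 0:
                return i + 0.5 * (y[i - 1] - y[i + 1]) / denom
        return float(i)

    v = window.voltages
    kernel = np.array([0.25, 0.5, 0.25])
    v = np.apply_along_axis(
        lambda y: np.convolve(np.pad(y, 1, mode="edge"), kernel, mode="valid"),
        0,
        v,
    )
    amps = np.ptp(v, axis=0)
    soma_amp = amps[window.soma_index]
    if soma_amp <= 0:
        raise ValueError("soma channel has no signal")
    dt_ms = 1000.0 / window.fs_hz
    ys = v[:, window.soma_index]
    soma_trough = _refine(ys, int(np.argmin(ys)))
    troughs = np.full(v.shape[1], np.nan)
    peaks = np.full(v.shape[1], np.nan)
    for j in range(v.shape[1]):
        if amps[j] < amplitude_floor_frac * soma_amp:
            continue
        y = v[:, j]
        troughs[j] = (_refine(y, int(np.argmin(y))) - soma_trough) * dt_ms
        peaks[j] = (_refine(y, int(np.argmax(y))) - soma_trough) * dt_ms
    return PropagationProfile(
        offsets_um=window.offsets_um.copy(),
        trough_times_ms=troughs,
        peak_times_ms=peaks,
    )


def unit_profile(template: WaveformTemplate, n_each_side: int = 5) -> PropagationProfile:
    """Window extraction + timing + per-unit slopes in one call."""
    prof = trough_peak_times(extract_window(template, n_each_side))
    prof.slope_above, prof.slope_below = propagation_slopes(
        prof.offsets_um, prof.trough_times_ms
    )
    if np.isfinite(prof.slope_above) and np.isfinite(prof.slope_below):
        prof.asymmetry = asymmetry_index(prof.slope_above, prof.slope_below)
    return prof


def cluster_trajectory(
    profiles: Sequence[PropagationProfile],
    min_units: int = 5,
) -> ClusterTrajectory:
    """Per-offset mean +/- SEM trough time with one-pass 95%-CI outlier removal.

    Values outside mean +/- 1.96 SD of the cluster's per-offset distribution
    are excluded once, then mean/SEM recomputed.  An offset where fewer than
    half the cluster's units report a time is unreliable (channels near the
    amplitude floor) and is reported as NaN.
    """
    if not profiles:
        raise ValueError("no profiles supplied")
    offsets = profiles[0].offsets_um
    for p in profiles[1:]:
        if not np.array_equal(p.offsets_um, offsets):
            raise ValueError("profiles must share a channel-offset grid")
    T = np.vstack([p.trough_times_ms for p in profiles])
    min_support = max(1, len(profiles) // 2)
    mean = np.full(offsets.size, np.nan)
    sem = np.full(offsets.size, np.nan)
    n_used = np.zeros(offsets.size, dtype=int)
    for j in range(offsets.size):
        vals = T[:, j]
        vals = vals[np.isfinite(vals)]
        if vals.size < min_support:
            continue
        if vals.size > 2:
            m, s = vals.mean(), vals.std(ddof=1)
            if s > 0:
                vals = vals[np.abs(vals - m) <= 1.96 * s]
        mean[j] = vals.mean()
        sem[j] = vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else 0.0
        n_used[j] = vals.size
    return ClusterTrajectory(offsets.copy(), mean, sem, n_used, low_n=len(profiles) < min_units)


def propagation_slopes(offsets_um, trough_times_ms) -> Tuple[float, float]:
    """OLS slopes (ms/um) of trough time vs signed distance, above and below.

    The soma point (0, 0) anchors both fits; a side with fewer than 3 finite
    points (soma included) yields NaN.
    """
    d = np.asarray(offsets_um, dtype=float)
    t = np.asarray(trough_times_ms, dtype=float)
    ok = np.isfinite(t)

    def fit(side_mask):
        m = ok & side_mask
        if m.sum() < 3:
            return np.nan
        return float(np.polyfit(d[m], t[m], 1)[0])

    return fit(d >= 0), fit(d <= 0)


def asymmetry_index(slope_above: float, slope_below: float) -> float:
    """Distance of (slope_above, slope_below) from the y = -x line.

    Zero for symmetric bidirectional propagation (equal speed away from the
    soma in both directions); |a + b| / sqrt(2) otherwise.
    """
    if not (np.isfinite(slope_above) and np.isfinite(slope_below)):
        return np.nan
    return abs(slope_above + slope_below) / np.sqrt(2.0)


def _slopes_of(profiles: Sequence[PropagationProfile]) -> Tuple[float, float, float]:
    traj = cluster_trajectory(profiles, min_units=1)
    sa, sb = propagation_slopes(traj.offsets_um, traj.mean_ms)
    return sa, sb, asymmetry_index(sa, sb)


def bootstrap_slope_tests(
    profiles: Sequence[PropagationProfile],
    n_boot: int = 500,
    seed=None,
) -> BootstrapSlopes:
    """Bootstrap (resampling units) SEs and CIs for cluster slopes.

    Reports the below-soma 95% percentile CI and whether it excludes zero
    (directionality test).  A single-unit cluster is degenerate and flagged.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    profiles = list(profiles)
    n = len(profiles)
    sa, sb, asym = _slopes_of(profiles)
    if n < 2:
        return BootstrapSlopes(sa, sb, asym, np.nan, np.nan, np.nan,
                               (np.nan, np.nan), False,
                               np.empty((0, 3)), degenerate=True)
    rng = as_rng(seed)
    reps = np.empty((n_boot, 3))
    for i in range(n_boot):
        take = rng.integers(0, n, size=n)
        reps[i] = _slopes_of([profiles[k] for k in take])
    se = np.nanstd(reps, axis=0, ddof=1)
    lo, hi = np.nanpercentile(reps[:, 1], [2.5, 97.5])
    return BootstrapSlopes(
        slope_above=sa,
        slope_below=sb,
        asymmetry=asym,
        se_above=float(se[0]),
        se_below=float(se[1]),
        se_asymmetry=float(se[2]),
        ci_below_95=(float(lo), float(hi)),
        below_excludes_zero=bool(lo > 0 or hi < 0),
        replicates=reps,
    )


def compare_asymmetry(
    profiles_a: Sequence[PropagationProfile],
    profiles_b: Sequence[PropagationProfile],
    n_boot: int = 500,
    level: float = 0.98,
    seed=None,
):
    """Independent bootstrap test of the asymmetry difference of two clusters.

    Returns ``(diff, (lo, hi), significant)`` with a percentile CI at
    ``level`` (98% by default, i.e. P < 0.02 when zero is excluded).
    """
    rng = as_rng(seed)
    a = list(profiles_a)
    b = list(profiles_b)
    diff = _slopes_of(a)[2] - _slopes_of(b)[2]
    reps = np.empty(n_boot)
    for i in range(n_boot):
        ra = [a[k] for k in rng.integers(0, len(a), size=len(a))]
        rb = [b[k] for k in rng.integers(0, len(b), size=len(b))]
        reps[i] = _slopes_of(ra)[2] - _slopes_of(rb)[2]
    alpha = 100 * (1 - level) / 2
    lo, hi = np.nanpercentile(reps, [alpha, 100 - alpha])
    return float(diff), (float(lo), float(hi)), bool(lo > 0 or hi < 0)
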