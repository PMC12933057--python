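"""Visual responsiveness and tuning metrics from drifting-grating trials.

Direction and orientation selectivity use the contrast-form indices
(preferred vs opposite / preferred vs orthogonal after folding directions
into orientations), computed on baseline-subtracted mean rates floored at
zero; vector-averaging variants are provided as alternatives.  Units with
index > 0.5 are conventionally called selective.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TuningCurve",
    "compute_tuning_curve",
    "responsiveness",
    "direction_index",
    "orientation_index",
    "vector_direction_index",
    "vector_orientation_index",
    "response_latency",
    "modulation_ratio",
    "modulation_ratio_from_rate",
]

SELECTIVITY_CUT = 0.5


@dataclass
class TuningCurve:
    """Mean direction-tuning curve of one unit at its best spatial frequency."""

    directions_deg: np.ndarray
    mean_rate_hz: np.ndarray
    sem_rate_hz: np.ndarray
    baseline_hz: float
    preferred_direction_deg: float
    dsi: float = np.nan
    osi: float = np.nan


def _preferred_direction(directions: np.ndarray, rates: np.ndarray) -> float:
    """Argmax of the 3-point circularly smoothed curve; ties -> lower angle."""
    sm = 0.5 * rates + 0.25 * np.roll(rates, 1) + 0.25 * np.roll(rates, -1)
    return float(directions[int(np.argmax(sm))])


def compute_tuning_curve(trials: pd.DataFrame, trial_duration_s: float,
                         baseline_duration_s: float) -> TuningCurve:
    """Tuning curve from a tidy trial table for a single unit.

    The spatial frequency with the highest overall mean response is selected;
    mean and SEM rates are per direction at that frequency.
    """
    by_sf = trials.groupby("spatial_frequency")["stimulus_count"].mean()
    best_sf = by_sf.idxmax()
    sel = trials[trials["spatial_frequency"] == best_sf]
    g = sel.groupby("direction_deg")["stimulus_count"]
    directions = np.asarray(sorted(g.groups), dtype=float)
    mean_rate = g.mean().loc[directions].to_numpy() / trial_duration_s
    sem_rate = g.sem().loc[directions].fillna(0.0).to_numpy() / trial_duration_s
    baseline = float(trials["baseline_count"].mean() / baseline_duration_s)
    curve = TuningCurve(
        directions_deg=directions,
        mean_rate_hz=mean_rate,
        sem_rate_hz=sem_rate,
        baseline_hz=baseline,
        preferred_direction_deg=_preferred_direction(directions, mean_rate),
    )
    curve.dsi = direction_index(curve)
    curve.osi = orientation_index(curve)
    return curve


def responsiveness(
    stimulus_counts,
    baseline_counts,
    stimulus_duration_s: float = 1.0,
    baseline_duration_s: float = 1.0,
    alpha: float = 0.05,
    min_evoked_hz: float = 1.0,
) -> Tuple[bool, float]:
    """Paired rank test of stimulus vs baseline rates plus an evoked-rate floor.

    Responsive iff the Wilcoxon signed-rank p < alpha AND the mean evoked
    rate exceeds baseline by at least ``min_evoked_hz``.
    """
    stim = np.asarray(stimulus_counts, dtype=float) / stimulus_duration_s
    base = np.asarray(baseline_counts, dtype=float) / baseline_duration_s
    if stim.size == 0 or base.size == 0:
        raise ValueError("need at least one trial in each condition")
    if stim.size != base.size:
        raise ValueError("paired comparison needs equal trial counts")
    diffs = stim - base
    if np.all(diffs == 0):
        p = 1.0
    else:
        p = float(sps.wilcoxon(stim, base, zero_method="wilcox").pvalue)
    evoked = float(stim.mean() - base.mean())
    return bool(p < alpha and evoked >= min_evoked_hz), p


def _rectified_rates(curve: TuningCurve) -> np.ndarray:
    return np.maximum(curve.mean_rate_hz - curve.baseline_hz, 0.0)


def _rate_at(curve: TuningCurve, rates: np.ndarray, direction: float) -> float:
    d = np.mod(direction, 360.0)
    i = int(np.argmin(np.abs(np.mod(curve.directions_deg - d + 180.0, 360.0) - 180.0)))
    return float(rates[i])


def direction_index(curve: TuningCurve) -> float:
    """DSI = (R_pref - R_null) / (R_pref + R_null), null 180 deg opposite.

    Rates are baseline-subtracted and floored at 0; returns NaN when both
    responses vanish.
    """
    r = _rectified_rates(curve)
    rp = _rate_at(curve, r, curve.preferred_direction_deg)
    rn = _rate_at(curve, r, curve.preferred_direction_deg + 180.0)
    if rp + rn == 0:
        return np.nan
    return (rp - rn) / (rp + rn)


def orientation_index(curve: TuningCurve) -> float:
    """OSI from the folded orientation curve: preferred vs orthogonal."""
    r = _rectified_rates(curve)

    def folded(direction):
        return 0.5 * (
            _rate_at(curve, r, direction) + _rate_at(curve, r, direction + 180.0)
        )

    rp = folded(curve.preferred_direction_deg)
    ro = folded(curve.preferred_direction_deg + 90.0)
    if rp + ro == 0:
        return np.nan
    return (rp - ro) / (rp + ro)


def vector_direction_index(curve: TuningCurve) -> float:
    """1 - circular variance over directions (vector-averaging alternative)."""
    r = _rectified_rates(curve)
    if r.sum() == 0:
        return np.nan
    z = np.sum(r * np.exp(1j * np.deg2rad(curve.directions_deg))) / r.sum()
    return float(np.abs(z))


def vector_orientation_index(curve: TuningCurve) -> float:
    """1 - circular variance on doubled angles (vector-averaging alternative)."""
    r = _rectified_rates(curve)
    if r.sum() == 0:
        return np.nan
    z = np.sum(r * np.exp(2j * np.deg2rad(curve.directions_deg))) / r.sum()
    return float(np.abs(z))


def response_latency(
    psth_rate_hz,
    bin_ms: float,
    onset_ms: float,
    baseline_mean_hz: float,
    baseline_sd_hz: float,
    n_consecutive: int = 2,
    n_sd: float = 3.0,
) -> float:
    """First PSTH bin after onset exceeding baseline + 3 SD for >= 2 bins.

    Returns the bin's start time in ms, or NaN when the rate never crosses.
    """
    if bin_ms > 5.0:
        raise ValueError("PSTH bin must be <= 5 ms for latency estimation")
    rate = np.asarray(psth_rate_hz, dtype=float)
    t = np.arange(rate.size) * bin_ms
    thresh = baseline_mean_hz + n_sd * baseline_sd_hz
    above = (rate > thresh) & (t >= onset_ms)
    for i in range(rate.size - n_consecutive + 1):
        if np.all(above[i:i + n_consecutive]):
            return float(t[i])
    return np.nan


def modulation_ratio(
    spike_times_s,
    t_start_s: float,
    t_stop_s: float,
    temporal_frequency_hz: float,
) -> float:
    """F1/F0 from spike times: first-harmonic amplitude over mean rate."""
    st = np.asarray(spike_times_s, dtype=float)
    st = st[(st >= t_start_s) & (st < t_stop_s)]
    duration = t_stop_s - t_start_s
    if duration <= 0:
        raise ValueError("empty analysis window")
    f0 = st.size / duration
    if f0 == 0:
        return np.nan
    f1 = 2.0 * np.abs(np.sum(np.exp(-2j * np.pi * temporal_frequency_hz * st))) / duration
    return float(f1 / f0)


def modulation_ratio_from_rate(rate_hz, dt_s: float, temporal_frequency_hz: float) -> float:
    """F1/F0 from a sampled rate trace (exact for noiseless rate models)."""
    r = np.asarray(rate_hz, dtype=float)
    t = np.arange(r.size) * dt_s
    f0 = r.mean()
    if f0 == 0:
        return np.nan
    f1 = 2.0 * np.abs(np.mean(r * np.exp(-2j * np.pi * temporal_frequency_hz * t)))
    return float(f1 / f0)
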