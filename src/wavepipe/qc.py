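"""Waveform curation: polarity, alignment, normalization, SNR, shape features.

Reimplements the semiautomatic quality-control math applied to spike-sorted
templates: pick the maximum-amplitude (somatic) channel, classify waveform
polarity (trough-first negative-spiking vs peak-first positive-spiking, with
triphasic shapes folded into the negative class), align negative waveforms to
the trough and positive ones to the peak, normalize into [-1, 1], and filter
on signal-to-noise ratio.  The manual-observer step of the original curation
is replaced by these deterministic shape/SNR rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "WINDOW_MS",
    "ALIGN_INDEX",
    "N_SAMPLES",
    "FlatWaveformError",
    "WaveformTemplate",
    "CuratedUnit",
    "max_channel",
    "classify_polarity",
    "align_and_normalize",
    "compute_snr",
    "trough_to_peak_duration",
    "curate",
]

#: Waveform window length (ms) and standard sample count at 30 kHz.
WINDOW_MS = 1.8
N_SAMPLES = 54
#: Sample index (of 54) the aligned extremum is moved to (0.6 ms).
ALIGN_INDEX = 18


class FlatWaveformError(ValueError):
    """Raised when a template carries no detectable extracellular spike."""


@dataclass
class WaveformTemplate:
    """Per-unit multichannel voltage template (samples x channels, uV)."""

    voltages: np.ndarray
    fs_hz: float
    channel_depths_um: np.ndarray
    unit_id: int = 0
    session_id: str = "s0"

    def __post_init__(self):
        self.voltages = np.asarray(self.voltages, dtype=float)
        self.channel_depths_um = np.asarray(self.channel_depths_um, dtype=float)
        if self.voltages.ndim != 2:
            raise ValueError("voltages must be samples x channels")
        if self.voltages.shape[1] != self.channel_depths_um.size:
            raise ValueError("one depth per channel required")
        d = np.diff(self.channel_depths_um)
        if self.channel_depths_um.size > 1 and not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("channel depths must be strictly monotonic")

    @property
    def n_samples(self) -> int:
        return self.voltages.shape[0]

    @property
    def n_channels(self) -> int:
        return self.voltages.shape[1]


@dataclass
class CuratedUnit:
    """Curated single unit: normalized somatic waveform plus scalar features."""

    unit_id: int
    waveform_norm: np.ndarray
    polarity: str
    n_phases: int
    amplitude_uv: float
    snr: float
    depth_um: float
    spike_times_s: np.ndarray = field(default_factory=lambda: np.empty(0))
    duration_ms: float = np.nan
    layer: Optional[str] = None
    visually_responsive: Optional[bool] = None
    alignment_padded: bool = False
    session_id: str = "s0"


def max_channel(template: WaveformTemplate):
    """Index of the channel with maximal peak-to-trough amplitude + its trace.

    Ties break toward the shallower channel. An all-zero template raises
    :class:`FlatWaveformError`.
    """
    amps = np.ptp(template.voltages, axis=0)
    if np.all(amps == 0):
        raise FlatWaveformError("template has no nonzero channel")
    best = np.flatnonzero(amps == amps.max())
    idx = int(best[np.argmin(template.channel_depths_um[best])])
    return idx, template.voltages[:, idx]


def classify_polarity(waveform: np.ndarray, triphasic_frac: float = 0.25):
    """Classify a somatic waveform as negative or positive spiking.

    Negative: trough precedes the dominant peak, or two major peaks (each at
    least ``triphasic_frac`` of the trough magnitude) flank the trough
    (triphasic, reported as 3 phases).  Positive: dominant peak precedes the
    trough.  The triphasic rule only applies to trough-dominated waveforms
    (|trough| >= |peak|), so a peak-first positive waveform with a small
    trough is never mistaken for triphasic.  Returns ``(polarity, n_phases)``.
    """
    w = np.asarray(waveform, dtype=float)
    if w.size < 3 or np.ptp(w) == 0:
        raise FlatWaveformError("no extremum above the noise floor")
    i_tr = int(np.argmin(w))
    trough_mag = abs(w[i_tr])
    pre = w[:i_tr].max(initial=-np.inf)
    post = w[i_tr + 1:].max(initial=-np.inf)
    if (
        trough_mag > 0
        and trough_mag >= w.max()
        and pre >= triphasic_frac * trough_mag
        and post >= triphasic_frac * trough_mag
    ):
        return "negative", 3
    i_pk = int(np.argmax(w))
    if w[i_pk] <= 0 and trough_mag == 0:
        raise FlatWaveformError("no extremum above the noise floor")
    return ("positive", 2) if i_pk < i_tr else ("negative", 2)


def align_and_normalize(
    waveform: np.ndarray,
    polarity: str,
    length: int = N_SAMPLES,
    align_index: int = ALIGN_INDEX,
):
    """Align the polarity-defining extremum to ``align_index`` and scale to [-1, 1].

    Negative-spiking waveforms are aligned to the trough, positive-spiking to
    the peak; the output is divided by its maximum absolute value so one
    extremum sits exactly at -1 or +1.  If the shift pushes the window past
    the recorded samples the edge value is repeated and the padded flag set.
    Returns ``(waveform_norm, padded)``.
    """
    w = np.asarray(waveform, dtype=float)
    if np.ptp(w) == 0:
        raise FlatWaveformError("cannot align a flat waveform")
    i_ext = int(np.argmin(w)) if polarity == "negative" else int(np.argmax(w))
    start = i_ext - align_index
    idx = np.arange(start, start + length)
    padded = bool(idx[0] < 0 or idx[-1] >= w.size)
    idx = np.clip(idx, 0, w.size - 1)
    out = w[idx]
    out = out / np.abs(out).max()
    return out, padded


def compute_snr(
    template: WaveformTemplate,
    residual_noise_sd: Optional[float] = None,
    noise_window_ms: float = 0.2,
) -> float:
    """Trough-to-peak amplitude on the max channel over the residual noise SD.

    When no noise SD is supplied it is estimated as the SD of the first
    ``noise_window_ms`` of the window pooled across channels (pre-spike
    baseline).  A zero template has SNR 0 by convention.
    """
    amps = np.ptp(template.voltages, axis=0)
    amp = float(amps.max())
    if residual_noise_sd is None:
        n = max(2, int(round(noise_window_ms * 1e-3 * template.fs_hz)))
        residual_noise_sd = float(np.std(template.voltages[:n, :]))
    if residual_noise_sd <= 0:
        raise ValueError("residual noise SD must be positive")
    return amp / residual_noise_sd


def trough_to_peak_duration(waveform: np.ndarray, fs_hz: float) -> float:
    """Time (ms) from the trough to the subsequent repolarization peak.

    Defined for negative-spiking waveforms; raises ``ValueError`` when the
    post-trough segment decays monotonically (no repolarization peak).
    """
    w = np.asarray(waveform, dtype=float)
    i_tr = int(np.argmin(w))
    seg = w[i_tr + 1:]
    if seg.size == 0:
        raise ValueError("trough at the last sample: no post-trough peak")
    if seg.size > 1 and np.all(np.diff(seg) <= 0):
        raise ValueError("no post-trough peak: waveform decays monotonically")
    i_pk = i_tr + 1 + int(np.argmax(seg))
    return (i_pk - i_tr) / fs_hz * 1000.0


def curate(
    templates: Sequence[WaveformTemplate],
    snr_min: float = 3.0,
    residual_noise_sd: Optional[float] = None,
    spike_times: Optional[dict] = None,
) -> list:
    """Run the full curation chain and keep units with snr >= snr_min.

    Flat/artifact templates (no extremum) are dropped; trough-to-peak duration
    is attached for negative-spiking survivors.
    """
    out = []
    for tpl in templates:
        try:
            ch, w = max_channel(tpl)
            polarity, n_phases = classify_polarity(w)
            wnorm, padded = align_and_normalize(w, polarity)
            snr = compute_snr(tpl, residual_noise_sd)
        except (FlatWaveformError, ValueError):
            continue
        if snr < snr_min:
            continue
        try:
            dur = trough_to_peak_duration(wnorm, tpl.fs_hz) if polarity == "negative" else np.nan
        except ValueError:
            dur = np.nan
        st = np.empty(0)
        if spike_times is not None:
            st = np.asarray(spike_times.get(tpl.unit_id, np.empty(0)), dtype=float)
        out.append(
            CuratedUnit(
                unit_id=tpl.unit_id,
                waveform_norm=wnorm,
                polarity=polarity,
                n_phases=n_phases,
                amplitude_uv=float(np.ptp(tpl.voltages[:, ch])),
                snr=snr,
                depth_um=float(tpl.channel_depths_um[ch]),
                spike_times_s=st,
                duration_ms=dur,
                alignment_padded=padded,
                session_id=tpl.session_id,
            )
        )
    return out
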