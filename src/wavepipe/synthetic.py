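"""Synthetic populations with ground truth for every analysis stage.

Emulates the statistical structure the pipeline assumes: multichannel spike
templates with parameterized trough-to-peak duration, polarity, exponential
amplitude decay over channels and linear trough-time propagation above/below
the soma; layered unit depths; renewal/bursting spike trains; von Mises
direction tuning over 36 drifting-grating directions; and directed or
common-input coupled spike-train pairs.  Every unit carries its generating
parameters so downstream estimates can be scored against truth.

The generator is deliberately phenomenological: waveforms are sums of
Gaussian lobes evaluated in continuous time (not cable-equation simulations),
spike trains are ISI-mixture renewal processes, and trial counts are Poisson
draws from the tuned rate.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .qc import WaveformTemplate
from .stats import as_rng

__all__ = [
    "TuningSpec",
    "GeneratorClassSpec",
    "StimulusProtocol",
    "CouplingEdge",
    "PopulationConfig",
    "SyntheticUnit",
    "SyntheticSession",
    "make_template",
    "simulate_spike_train",
    "solve_kappas",
    "tuned_rate",
    "analytic_indices",
    "simulate_tuned_trials",
    "simulate_coupled_pair",
    "build_population",
    "default_config",
]


# --------------------------------------------------------------------------
# specifications


@dataclass(frozen=True)
class TuningSpec:
    """Direction-tuning targets for one generator class."""

    preferred_direction_deg: float = 90.0
    osi_target: float = 0.5
    dsi_target: float = 0.3
    baseline_hz: float = 5.0
    peak_hz: float = 25.0


@dataclass(frozen=True)
class GeneratorClassSpec:
    """Generative parameters of one candidate cell-type class.

    ``v_above_ms_per_um`` / ``v_below_ms_per_um`` are the slopes of trough
    time versus signed distance from the soma (positive distances above the
    soma, i.e. shallower channels); amplitude decays as
    ``exp(-d / amplitude_space_constant_um)`` with channel distance.
    """

    name: str
    polarity: str = "negative"
    phases: str = "biphasic"
    trough_to_peak_ms: float = 0.4
    amplitude_uv: float = 100.0
    layer_probs: Tuple[float, ...] = (0.2, 0.2, 0.2, 0.2, 0.2)
    v_above_ms_per_um: float = 0.002
    v_below_ms_per_um: float = -0.002
    amplitude_space_constant_um: float = 40.0
    burstiness: float = 0.0
    tuning: TuningSpec = field(default_factory=TuningSpec)
    rate_hz: Optional[float] = None  # spontaneous-train rate; default baseline
    repolarization_ratio: float = 0.35  # repolarization peak / trough depth

    def __post_init__(self):
        p = np.asarray(self.layer_probs, dtype=float)
        if abs(p.sum() - 1.0) > 1e-9 or np.any(p < 0):
            raise ValueError(f"layer_probs of {self.name} must sum to 1")
        if self.trough_to_peak_ms <= 0:
            raise ValueError("trough_to_peak_ms must be positive")
        if self.amplitude_uv <= 0:
            raise ValueError("amplitude_uv must be positive")
        if self.amplitude_space_constant_um <= 0:
            raise ValueError("amplitude_space_constant_um must be positive")
        if not 0 <= self.burstiness <= 1:
            raise ValueError("burstiness must be in [0, 1]")
        if self.polarity not in ("negative", "positive"):
            raise ValueError("polarity must be 'negative' or 'positive'")
        if self.phases not in ("biphasic", "triphasic"):
            raise ValueError("phases must be 'biphasic' or 'triphasic'")

    @property
    def spont_rate_hz(self) -> float:
        return self.rate_hz if self.rate_hz is not None else self.tuning.baseline_hz


@dataclass(frozen=True)
class StimulusProtocol:
    """Drifting-grating protocol: 36 directions x 4 spatial frequencies."""

    directions_deg: Tuple[float, ...] = tuple(float(d) for d in range(0, 360, 10))
    spatial_frequencies: Tuple[float, ...] = (0.5, 1.0, 2.0, 4.0)
    trials_per_condition: int = 10
    trial_duration_s: float = 1.0
    baseline_duration_s: float = 0.5
    temporal_frequency_hz: float = 4.0

    def __post_init__(self):
        d = np.asarray(self.directions_deg, dtype=float)
        step = 360.0 / d.size
        if not np.allclose(d, np.arange(d.size) * step):
            raise ValueError("directions must equally tile [0, 360)")
        if self.trials_per_condition < 1:
            raise ValueError("trials_per_condition must be >= 1")
        if self.trial_duration_s <= 0 or self.baseline_duration_s <= 0:
            raise ValueError("durations must be positive")


# --------------------------------------------------------------------------
# multichannel templates


def _lobe(t, center, sd):
    return np.exp(-0.5 * ((t - center) / sd) ** 2)


def _waveform_shape(t_ms: np.ndarray, spec: GeneratorClassSpec, t_trough_ms: float):
    """Continuous-time somatic waveform (unit peak-to-trough amplitude).

    A narrow Gaussian trough followed by a broader repolarization peak at
    ``trough_to_peak_ms``; triphasic classes add a pre-trough peak.  Positive
    polarity flips the sign (capacitive, peak-first waveforms).
    """
    ttp = spec.trough_to_peak_ms
    sd_tr = max(0.04, 0.15 * ttp)
    sd_pk = max(0.08, 0.35 * ttp)
    w = -_lobe(t_ms, t_trough_ms, sd_tr) + spec.repolarization_ratio * _lobe(
        t_ms, t_trough_ms + ttp, sd_pk
    )
    if spec.phases == "triphasic":
        w = w + 0.35 * _lobe(t_ms, t_trough_ms - 0.25, 0.10)
    if spec.polarity == "positive":
        w = -w
    return w / np.ptp(w) if np.ptp(w) > 0 else w


def make_template(
    spec: GeneratorClassSpec,
    depth_um: float,
    n_channels: int = 11,
    pitch_um: float = 20.0,
    fs_hz: float = 30000.0,
    noise_sd: float = 0.0,
    seed=None,
    window_ms: float = 1.8,
    t_trough_ms: float = 0.6,
    unit_id: int = 0,
    session_id: str = "s0",
) -> WaveformTemplate:
    """Build a multichannel template whose max-amplitude channel is the soma.

    The soma sits on the center channel at ``depth_um``.  On a channel at
    signed distance ``d`` from the soma (positive above, i.e. shallower) the
    trough is shifted by ``v_above*d`` (``v_below*d`` below) and the
    amplitude scaled by ``exp(-|d|/space_constant)``.  Gaussian noise of SD
    ``noise_sd`` (uV) is added last.
    """
    if fs_hz <= 0 or pitch_um <= 0:
        raise ValueError("fs_hz and pitch_um must be positive")
    if n_channels < 1 or n_channels % 2 == 0:
        raise ValueError("n_channels must be odd so the soma is centered")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    n_samples = int(round(window_ms * 1e-3 * fs_hz))
    t_ms = np.arange(n_samples) / fs_hz * 1000.0
    half = n_channels // 2
    # depths ascending: shallowest (above soma) first
    depths = depth_um + (np.arange(n_channels) - half) * pitch_um
    offsets = depth_um - depths  # positive above the soma
    volts = np.empty((n_samples, n_channels))
    for j, d in enumerate(offsets):
        v = spec.v_above_ms_per_um if d > 0 else spec.v_below_ms_per_um
        shift = v * d
        amp = spec.amplitude_uv * np.exp(-abs(d) / spec.amplitude_space_constant_um)
        volts[:, j] = amp * _waveform_shape(t_ms - shift, spec, t_trough_ms)
    if noise_sd > 0:
        volts = volts + as_rng(seed).normal(0.0, noise_sd, size=volts.shape)
    return WaveformTemplate(
        voltages=volts,
        fs_hz=fs_hz,
        channel_depths_um=depths,
        unit_id=unit_id,
        session_id=session_id,
    )


# --------------------------------------------------------------------------
# spike trains

#: Gamma burst-ISI component: shape 2, scale 2 ms -> mode 2 ms, mean 4 ms.
_BURST_SHAPE = 2.0
_BURST_SCALE_MS = 2.0


def simulate_spike_train(
    rate_hz: float,
    burstiness: float,
    duration_s: float,
    seed=None,
    refractory_ms: float = 1.0,
) -> np.ndarray:
    """Renewal spike train with an ISI-mixture burst mechanism.

    With probability ``burstiness`` an ISI is drawn from a short gamma
    component (refractory + Gamma(2, 2 ms), mode 2 ms); otherwise from
    refractory + exponential.  The exponential mean is set so the mixture
    mean ISI equals ``1/rate_hz`` exactly.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if rate_hz <= 0:
        raise ValueError("rate_hz must be positive")
    if not 0 <= burstiness <= 1:
        raise ValueError("burstiness must be in [0, 1]")
    rng = as_rng(seed)
    target_ms = 1000.0 / rate_hz
    burst_mean = refractory_ms + _BURST_SHAPE * _BURST_SCALE_MS
    exp_mass = 1.0 - burstiness
    exp_mean = (
        (target_ms - burstiness * burst_mean) / exp_mass - refractory_ms
        if exp_mass > 0
        else np.nan
    )
    if exp_mass == 0 or exp_mean <= 0:
        raise ValueError(
            "rate_hz too high for the burst mixture: mean ISI must exceed "
            f"{burstiness * burst_mean + exp_mass * refractory_ms:.2f} ms"
        )
    times = []
    t = 0.0
    total_ms = duration_s * 1000.0
    while t < total_ms:
        n = max(64, int((total_ms - t) / target_ms * 1.2) + 16)
        is_burst = rng.random(n) < burstiness
        isi = np.where(
            is_burst,
            refractory_ms + rng.gamma(_BURST_SHAPE, _BURST_SCALE_MS, size=n),
            refractory_ms + rng.exponential(exp_mean, size=n),
        )
        chunk = t + np.cumsum(isi)
        times.append(chunk)
        t = chunk[-1]
    spikes = np.concatenate(times)
    return spikes[spikes < total_ms] / 1000.0


# --------------------------------------------------------------------------
# tuning

_KAPPA_D_MAX = 20.0
_KAPPA_O_MAX = 400.0


def solve_kappas(dsi_target: float, osi_target: float) -> Tuple[float, float]:
    """Concentrations (kappa_d, kappa_o) hitting the DSI/OSI targets.

    The rate model is ``baseline + (peak-baseline) *
    exp(kappa_d(cos(x)-1) + kappa_o(cos(2x)-1))`` with ``x`` the angle from
    the preferred direction.  Under the contrast-form indices (pref vs null;
    pref vs orthogonal after folding directions into orientations) the
    targets give closed forms: ``kappa_d = atanh(DSI)`` and ``kappa_o``
    from the folded orientation contrast.  An OSI target below
    ``tanh^2(kappa_d / 2)`` is unreachable (direction tuning alone already
    yields that much orientation contrast) and raises ``ValueError``.
    """
    for name, v in (("dsi_target", dsi_target), ("osi_target", osi_target)):
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must be in [0, 1]")
    kappa_d = float(np.arctanh(min(dsi_target, 1 - 1e-16)))
    kappa_d = min(kappa_d, _KAPPA_D_MAX)
    a = np.exp(-kappa_d)
    osi_floor = np.tanh(kappa_d / 2.0) ** 2
    if osi_target < osi_floor - 1e-9:
        raise ValueError(
            f"osi_target {osi_target:.4f} below achievable floor "
            f"{osi_floor:.4f} = tanh^2(atanh(dsi)/2) for dsi_target {dsi_target:.4f}"
        )
    if osi_target >= 1 - 1e-16:
        return kappa_d, _KAPPA_O_MAX
    u = (1 + a**2) / (2 * a) * (1 - osi_target) / (1 + osi_target)
    u = min(u, 1.0)
    kappa_o = min(-0.5 * np.log(max(u, np.exp(-2 * _KAPPA_O_MAX))), _KAPPA_O_MAX)
    return kappa_d, float(kappa_o)


def tuned_rate(spec: GeneratorClassSpec, directions_deg) -> np.ndarray:
    """Noiseless firing rate (Hz) of the class at the given directions."""
    t = spec.tuning
    kappa_d, kappa_o = solve_kappas(t.dsi_target, t.osi_target)
    x = np.deg2rad(np.asarray(directions_deg, dtype=float) - t.preferred_direction_deg)
    g = np.exp(kappa_d * (np.cos(x) - 1) + kappa_o * (np.cos(2 * x) - 1))
    return t.baseline_hz + (t.peak_hz - t.baseline_hz) * g


def analytic_indices(dsi_target: float, osi_target: float) -> Tuple[float, float]:
    """DSI/OSI of the noiseless rate model for the solved concentrations."""
    kappa_d, kappa_o = solve_kappas(dsi_target, osi_target)
    a = np.exp(-kappa_d)
    dsi = (1 - a**2) / (1 + a**2)  # == tanh(kappa_d)
    r_pref = (1 + a**2) / 2.0
    r_orth = a * np.exp(-2 * kappa_o)
    osi = (r_pref - r_orth) / (r_pref + r_orth)
    return float(dsi), float(osi)


def simulate_tuned_trials(
    spec: GeneratorClassSpec,
    protocol: StimulusProtocol,
    seed=None,
    unit_id: int = 0,
) -> pd.DataFrame:
    """Poisson trial counts from the von Mises rate model.

    Returns a tidy table with one row per (direction, spatial frequency,
    trial): ``stimulus_count`` over ``trial_duration_s`` and
    ``baseline_count`` over ``baseline_duration_s``.
    """
    rng = as_rng(seed)
    dirs = np.asarray(protocol.directions_deg, dtype=float)
    rates = tuned_rate(spec, dirs)
    rows = []
    for sf in protocol.spatial_frequencies:
        lam_stim = rates * protocol.trial_duration_s
        lam_base = spec.tuning.baseline_hz * protocol.baseline_duration_s
        for trial in range(protocol.trials_per_condition):
            stim = rng.poisson(lam_stim)
            base = rng.poisson(lam_base, size=dirs.size)
            for d, s, b in zip(dirs, stim, base):
                rows.append((unit_id, d, sf, trial, int(s), int(b)))
    return pd.DataFrame(
        rows,
        columns=[
            "unit_id",
            "direction_deg",
            "spatial_frequency",
            "trial",
            "stimulus_count",
            "baseline_count",
        ],
    )


# --------------------------------------------------------------------------
# coupled pairs


def simulate_coupled_pair(
    source: np.ndarray,
    mode: str = "directed",
    delay_ms: float = 2.0,
    efficacy: float = 0.1,
    jitter_ms: float = 0.3,
    seed=None,
    duration_s: Optional[float] = None,
    background_rate_hz: float = 10.0,
    refractory_ms: float = 1.0,
) -> np.ndarray:
    """Target spike train coupled to ``source``.

    directed: each source spike induces a target spike with probability
    ``efficacy`` at ``+delay_ms`` (Gaussian jitter), superposed on an
    independent background train.  common_input: induced spikes at lag ~0.
    independent: background only.
    """
    if mode not in ("directed", "common_input", "independent"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "directed" and delay_ms <= 0:
        raise ValueError("delay_ms must be positive in directed mode")
    if not 0 <= efficacy <= 1:
        raise ValueError("efficacy must be in [0, 1]")
    source = np.asarray(source, dtype=float)
    if duration_s is None:
        duration_s = float(source[-1]) if source.size else 1.0
    rng = as_rng(seed)
    target = simulate_spike_train(
        background_rate_hz, 0.0, duration_s, seed=rng, refractory_ms=refractory_ms
    )
    if mode != "independent" and efficacy > 0 and source.size:
        keep = source[rng.random(source.size) < efficacy]
        offset = delay_ms / 1000.0 if mode == "directed" else 0.0
        induced = keep + offset + rng.normal(0.0, jitter_ms / 1000.0, size=keep.size)
        target = np.concatenate([target, induced])
    target = np.sort(target[(target >= 0) & (target < duration_s)])
    if target.size > 1:  # enforce refractoriness after superposition
        keep_mask = np.concatenate([[True], np.diff(target) >= refractory_ms / 1000.0])
        target = target[keep_mask]
    return target


# --------------------------------------------------------------------------
# whole sessions


@dataclass(frozen=True)
class CouplingEdge:
    source: int
    target: int
    mode: str = "directed"
    delay_ms: float = 2.0
    efficacy: float = 0.1
    jitter_ms: float = 0.3

    def __post_init__(self):
        if self.mode == "directed" and self.delay_ms <= 0:
            raise ValueError("coupling delays must be positive")


@dataclass
class PopulationConfig:
    """Complete recipe for a synthetic session."""

    classes: List[Tuple[GeneratorClassSpec, int]]
    layer_names: Tuple[str, ...] = ("L2/3", "L4a/4b", "L4c", "L5/6", "WM")
    layer_edges_um: Tuple[float, ...] = (0.0, 550.0, 750.0, 1100.0, 1600.0)
    wm_thickness_um: float = 200.0
    protocol: StimulusProtocol = field(default_factory=StimulusProtocol)
    coupling: List[CouplingEdge] = field(default_factory=list)
    train_duration_s: float = 300.0
    n_channels: int = 11
    pitch_um: float = 20.0
    fs_hz: float = 30000.0
    template_noise_sd_uv: float = 0.0
    session_id: str = "synthetic"

    def __post_init__(self):
        if not self.classes:
            raise ValueError("config must list at least one generator class")
        edges = np.asarray(self.layer_edges_um, dtype=float)
        if np.any(np.diff(edges) <= 0):
            raise ValueError("layer edges must be strictly increasing")
        n_layers = len(self.layer_names)
        if edges.size != n_layers:  # K gray layers need K edges; WM open-ended
            raise ValueError("need one top edge per layer (WM open below)")
        for spec, n in self.classes:
            if len(spec.layer_probs) != n_layers:
                raise ValueError(f"layer_probs of {spec.name} must have {n_layers} entries")
            if n < 1:
                raise ValueError("unit counts must be positive")


@dataclass
class SyntheticUnit:
    unit_id: int
    template: WaveformTemplate
    spike_times_s: np.ndarray
    class_name: str
    depth_um: float
    layer: str


@dataclass
class SyntheticSession:
    units: List[SyntheticUnit]
    ground_truth: pd.DataFrame
    trials: pd.DataFrame
    config: PopulationConfig
    seed: int

    def digest(self) -> str:
        """Content hash over templates, trains, truth and trials."""
        h = hashlib.sha256()
        for u in self.units:
            h.update(np.ascontiguousarray(u.template.voltages).tobytes())
            h.update(np.ascontiguousarray(u.spike_times_s).tobytes())
        h.update(self.ground_truth.to_csv(index=False).encode())
        h.update(self.trials.to_csv(index=False).encode())
        return h.hexdigest()


def _draw_depth(rng, config: PopulationConfig, layer_idx: int) -> float:
    edges = np.asarray(config.layer_edges_um, dtype=float)
    top = edges[layer_idx]
    bottom = (
        edges[layer_idx + 1]
        if layer_idx + 1 < edges.size
        else edges[-1] + config.wm_thickness_um
    )
    depth = rng.uniform(top, bottom)
    # snap to the channel grid so the soma sits on a real recording site,
    # clamping to grid points inside the drawn layer
    pitch = config.pitch_um
    lo = np.ceil(top / pitch) * pitch
    hi = np.floor((bottom - 1e-9) / pitch) * pitch
    return float(np.clip(np.round(depth / pitch) * pitch, lo, hi))


def build_population(config: PopulationConfig, seed: int = 0) -> SyntheticSession:
    """Draw a full synthetic session with per-unit ground truth.

    Unit depths are drawn from each class's layer probabilities within the
    supplied boundaries; spike trains use each class's burstiness and
    spontaneous rate; coupling edges replace the target unit's train with a
    coupled one.  Identical (config, seed) gives an identical session.
    """
    rng = as_rng(seed)
    units: List[SyntheticUnit] = []
    rows = []
    trials = []
    uid = 0
    for spec, n_units in config.classes:
        probs = np.asarray(spec.layer_probs, dtype=float)
        for _ in range(n_units):
            layer_idx = int(rng.choice(probs.size, p=probs))
            depth = _draw_depth(rng, config, layer_idx)
            tpl = make_template(
                spec,
                depth,
                n_channels=config.n_channels,
                pitch_um=config.pitch_um,
                fs_hz=config.fs_hz,
                noise_sd=config.template_noise_sd_uv,
                seed=rng,
                unit_id=uid,
                session_id=config.session_id,
            )
            train = simulate_spike_train(
                spec.spont_rate_hz, spec.burstiness, config.train_duration_s, seed=rng
            )
            units.append(
                SyntheticUnit(uid, tpl, train, spec.name, depth, config.layer_names[layer_idx])
            )
            trials.append(simulate_tuned_trials(spec, config.protocol, seed=rng, unit_id=uid))
            rows.append(
                dict(
                    unit_id=uid,
                    class_name=spec.name,
                    polarity=spec.polarity,
                    phases=spec.phases,
                    depth_um=depth,
                    layer=config.layer_names[layer_idx],
                    trough_to_peak_ms=spec.trough_to_peak_ms,
                    amplitude_uv=spec.amplitude_uv,
                    v_above_ms_per_um=spec.v_above_ms_per_um,
                    v_below_ms_per_um=spec.v_below_ms_per_um,
                    burstiness=spec.burstiness,
                    preferred_direction_deg=spec.tuning.preferred_direction_deg,
                    osi_target=spec.tuning.osi_target,
                    dsi_target=spec.tuning.dsi_target,
                    baseline_hz=spec.tuning.baseline_hz,
                    peak_hz=spec.tuning.peak_hz,
                    rate_hz=spec.spont_rate_hz,
                )
            )
            uid += 1
    for edge in config.coupling:
        if not (0 <= edge.source < uid and 0 <= edge.target < uid):
            raise ValueError("coupling edge references an absent unit")
        src = units[edge.source]
        tgt = units[edge.target]
        tgt.spike_times_s = simulate_coupled_pair(
            src.spike_times_s,
            mode=edge.mode,
            delay_ms=edge.delay_ms,
            efficacy=edge.efficacy,
            jitter_ms=edge.jitter_ms,
            seed=rng,
            duration_s=config.train_duration_s,
            background_rate_hz=next(
                s.spont_rate_hz for s, _ in config.classes
                if s.name == tgt.class_name
            ),
        )
    ground_truth = pd.DataFrame(rows)
    return SyntheticSession(
        units=units,
        ground_truth=ground_truth,
        trials=pd.concat(trials, ignore_index=True),
        config=config,
        seed=int(seed) if np.isscalar(seed) else 0,
    )


def waveform_bank(
    n_per_class: int = 100,
    noise_frac: float = 0.1,
    seed=0,
    classes: Optional[Sequence[GeneratorClassSpec]] = None,
):
    """Curated normalized waveforms from the default classes, with truth.

    Each template gets white noise of SD ``noise_frac`` times its class
    amplitude, then passes through the curation math (max channel, polarity,
    alignment, normalization).  Returns ``(waveforms, class_labels,
    durations_ms)`` for clustering-recovery studies.
    """
    from . import qc as _qc

    if classes is None:
        classes = [spec for spec, _ in default_config().classes]
    rng = as_rng(seed)
    W, labels, durations = [], [], []
    for spec in classes:
        for _ in range(n_per_class):
            tpl = make_template(
                spec, 500.0, noise_sd=noise_frac * spec.amplitude_uv, seed=rng
            )
            _, w = _qc.max_channel(tpl)
            polarity, _ = _qc.classify_polarity(w)
            wnorm, _ = _qc.align_and_normalize(w, polarity)
            W.append(wnorm)
            labels.append(spec.name)
            try:
                durations.append(_qc.trough_to_peak_duration(wnorm, tpl.fs_hz))
            except ValueError:
                durations.append(np.nan)
    return np.vstack(W), np.asarray(labels), np.asarray(durations)


def default_config(
    units_per_class: int = 25,
    train_duration_s: float = 240.0,
    trials_per_condition: int = 5,
    template_noise_sd_uv: float = 2.0,
) -> PopulationConfig:
    """The default six-class study population.

    Classes emulate the families the analysis is built to separate: four
    narrow/broad biphasic negative-spiking classes with distinct
    trough-to-peak durations, laminar homes, burstiness and tuning, one
    triphasic class, and one positive-spiking (white-matter-like) class.
    """
    ns1 = GeneratorClassSpec(
        name="NS-1",
        trough_to_peak_ms=0.27,
        amplitude_uv=90.0,
        layer_probs=(0.05, 0.25, 0.6, 0.1, 0.0),
        v_above_ms_per_um=0.002,
        v_below_ms_per_um=-0.002,
        burstiness=0.8,
        tuning=TuningSpec(90.0, 0.8, 0.2, 8.0, 30.0),
        repolarization_ratio=0.55,
    )
    ns3 = GeneratorClassSpec(
        name="NS-3",
        trough_to_peak_ms=0.20,
        amplitude_uv=150.0,
        layer_probs=(0.05, 0.6, 0.25, 0.1, 0.0),
        v_above_ms_per_um=0.0025,
        v_below_ms_per_um=-0.001,
        burstiness=0.2,
        tuning=TuningSpec(180.0, 0.8, 0.8, 8.0, 35.0),
        repolarization_ratio=0.25,
    )
    bs1 = GeneratorClassSpec(
        name="BS-1",
        trough_to_peak_ms=0.50,
        amplitude_uv=80.0,
        layer_probs=(0.6, 0.1, 0.1, 0.2, 0.0),
        v_above_ms_per_um=0.0015,
        v_below_ms_per_um=-0.0015,
        burstiness=0.1,
        tuning=TuningSpec(0.0, 0.5, 0.3, 6.0, 20.0),
    )
    bs4 = GeneratorClassSpec(
        name="BS-4",
        trough_to_peak_ms=0.70,
        amplitude_uv=70.0,
        layer_probs=(0.1, 0.05, 0.05, 0.8, 0.0),
        v_above_ms_per_um=0.001,
        v_below_ms_per_um=0.001,
        burstiness=0.0,
        tuning=TuningSpec(270.0, 0.4, 0.2, 6.0, 18.0),
        repolarization_ratio=0.5,
    )
    tp1 = GeneratorClassSpec(
        name="TP-1",
        phases="triphasic",
        trough_to_peak_ms=0.30,
        amplitude_uv=60.0,
        layer_probs=(0.2, 0.2, 0.3, 0.3, 0.0),
        v_above_ms_per_um=0.003,
        v_below_ms_per_um=0.003,
        burstiness=0.1,
        tuning=TuningSpec(45.0, 0.4, 0.3, 7.0, 22.0),
    )
    pos = GeneratorClassSpec(
        name="POS-1",
        polarity="positive",
        trough_to_peak_ms=0.45,
        amplitude_uv=60.0,
        layer_probs=(0.0, 0.0, 0.0, 0.2, 0.8),
        v_above_ms_per_um=0.001,
        v_below_ms_per_um=-0.001,
        burstiness=0.0,
        tuning=TuningSpec(0.0, 0.1, 0.05, 5.0, 8.0),
    )
    protocol = StimulusProtocol(trials_per_condition=trials_per_condition)
    coupling = [
        CouplingEdge(source=0, target=3 * units_per_class, mode="directed",
                     delay_ms=2.0, efficacy=0.15),
        CouplingEdge(source=1, target=3 * units_per_class + 1, mode="directed",
                     delay_ms=3.0, efficacy=0.15),
        CouplingEdge(source=2, target=2 * units_per_class, mode="common_input",
                     delay_ms=1.0, efficacy=0.15),
    ]
    return PopulationConfig(
        classes=[(ns1, units_per_class), (ns3, units_per_class), (bs1, units_per_class),
                 (bs4, units_per_class), (tp1, units_per_class), (pos, units_per_class)],
        protocol=protocol,
        coupling=coupling,
        train_duration_s=train_duration_s,
        template_noise_sd_uv=template_noise_sd_uv,
    )
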