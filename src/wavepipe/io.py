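"""Session readers/writers in a Kilosort/phy-style directory layout.

A session directory holds flat ``.npy`` arrays readable by the phy
ecosystem — ``templates.npy`` (units x samples x channels, uV),
``spike_times.npy`` (seconds), ``spike_clusters.npy`` (per-spike unit
index), ``channel_positions.npy`` (channels x 2, the second column the
depth in um) — plus TSV tables (layer boundaries, trials, optional ground
truth) and a YAML config/provenance file.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from .qc import WaveformTemplate

__all__ = ["SessionBundle", "write_session", "read_sorted_session"]

_REQUIRED = [
    "templates.npy",
    "spike_times.npy",
    "spike_clusters.npy",
    "channel_positions.npy",
]


@dataclass
class SessionBundle:
    """Validated in-memory session: templates, trains, tables, provenance."""

    templates: List[WaveformTemplate]
    spike_trains: Dict[int, np.ndarray]
    channel_depths_um: np.ndarray
    boundaries: Optional[pd.DataFrame] = None
    trials: Optional[pd.DataFrame] = None
    ground_truth: Optional[pd.DataFrame] = None
    provenance: dict = field(default_factory=dict)

    def digest(self) -> str:
        h = hashlib.sha256()
        for tpl in self.templates:
            h.update(np.ascontiguousarray(tpl.voltages).tobytes())
        for uid in sorted(self.spike_trains):
            h.update(np.ascontiguousarray(self.spike_trains[uid]).tobytes())
        h.update(np.ascontiguousarray(self.channel_depths_um).tobytes())
        for df in (self.boundaries, self.trials, self.ground_truth):
            if df is not None:
                h.update(df.to_csv(index=False).encode())
        return h.hexdigest()


def write_session(session, directory, boundaries: Optional[pd.DataFrame] = None):
    """Write a synthetic session to a phy-style directory.

    Per-unit local templates are embedded into a common probe channel map
    spanning all recorded depths at the session pitch; channels a unit does
    not cover are zero.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pitch = session.config.pitch_um
    all_depths = np.concatenate([u.template.channel_depths_um for u in session.units])
    grid = np.arange(all_depths.min(), all_depths.max() + pitch / 2, pitch)
    n_samples = session.units[0].template.n_samples
    templates = np.zeros((len(session.units), n_samples, grid.size))
    for i, u in enumerate(session.units):
        cols = np.rint((u.template.channel_depths_um - grid[0]) / pitch).astype(int)
        templates[i][:, cols] = u.template.voltages
    np.save(directory / "templates.npy", templates)
    times = np.concatenate([u.spike_times_s for u in session.units])
    clusters = np.concatenate(
        [np.full(u.spike_times_s.size, u.unit_id) for u in session.units]
    )
    order = np.argsort(times, kind="stable")
    np.save(directory / "spike_times.npy", times[order])
    np.save(directory / "spike_clusters.npy", clusters[order].astype(np.int64))
    positions = np.column_stack([np.zeros(grid.size), grid])
    np.save(directory / "channel_positions.npy", positions)
    if boundaries is None:
        edges = list(session.config.layer_edges_um)
        rows = []
        for i, name in enumerate(session.config.layer_names):
            bottom = (
                edges[i + 1]
                if i + 1 < len(edges)
                else edges[-1] + session.config.wm_thickness_um
            )
            rows.append((session.config.session_id, name, edges[i], bottom))
        boundaries = pd.DataFrame(
            rows, columns=["session_id", "layer", "top_um", "bottom_um"]
        )
    boundaries.to_csv(directory / "layer_boundaries.tsv", sep="\t", index=False)
    session.trials.to_csv(directory / "trials.tsv", sep="\t", index=False)
    session.ground_truth.to_csv(directory / "ground_truth.tsv", sep="\t", index=False)
    provenance = {
        "session_id": session.config.session_id,
        "seed": session.seed,
        "fs_hz": session.config.fs_hz,
        "pitch_um": pitch,
        "train_duration_s": session.config.train_duration_s,
        "digest": session.digest(),
    }
    with open(directory / "config.yaml", "w") as fh:
        yaml.safe_dump(provenance, fh)
    return directory


def read_sorted_session(directory) -> SessionBundle:
    """Read and validate a phy-style session directory.

    Raises a named error for missing files and shape mismatches; spike times
    are sorted per unit, and units without spikes are dropped with a warning.
    """
    import warnings

    directory = Path(directory)
    for name in _REQUIRED:
        if not (directory / name).exists():
            raise FileNotFoundError(f"session directory is missing {name}")
    templates = np.load(directory / "templates.npy")
    spike_times = np.load(directory / "spike_times.npy")
    spike_clusters = np.load(directory / "spike_clusters.npy")
    positions = np.load(directory / "channel_positions.npy")
    if templates.ndim != 3:
        raise ValueError(
            f"templates.npy must be units x samples x channels, got shape {templates.shape}"
        )
    if positions.ndim != 2 or positions.shape[0] != templates.shape[2]:
        raise ValueError(
            "channel_positions.npy rows must match template channels: "
            f"expected {templates.shape[2]}, got {positions.shape[0]}"
        )
    if spike_times.shape != spike_clusters.shape:
        raise ValueError(
            "spike_times.npy and spike_clusters.npy must align: "
            f"{spike_times.shape} vs {spike_clusters.shape}"
        )
    n_units = templates.shape[0]
    bad = np.setdiff1d(np.unique(spike_clusters), np.arange(n_units))
    if bad.size:
        raise ValueError(f"spike labels reference absent units: {bad.tolist()}")
    depths = positions[:, 1].astype(float)
    fs_hz = 30000.0
    provenance = {}
    cfg = directory / "config.yaml"
    if cfg.exists():
        with open(cfg) as fh:
            provenance = yaml.safe_load(fh) or {}
        fs_hz = float(provenance.get("fs_hz", fs_hz))
    bundle_templates = []
    spike_trains = {}
    for uid in range(n_units):
        st = np.sort(spike_times[spike_clusters == uid].astype(float))
        if st.size == 0:
            warnings.warn(f"unit {uid} has no spikes and was dropped")
            continue
        bundle_templates.append(
            WaveformTemplate(
                voltages=templates[uid],
                fs_hz=fs_hz,
                channel_depths_um=depths,
                unit_id=uid,
                session_id=str(provenance.get("session_id", directory.name)),
            )
        )
        spike_trains[uid] = st
    boundaries = trials = truth = None
    if (directory / "layer_boundaries.tsv").exists():
        boundaries = pd.read_csv(directory / "layer_boundaries.tsv", sep="\t")
    if (directory / "trials.tsv").exists():
        trials = pd.read_csv(directory / "trials.tsv", sep="\t")
    if (directory / "ground_truth.tsv").exists():
        truth = pd.read_csv(directory / "ground_truth.tsv", sep="\t")
    return SessionBundle(
        templates=bundle_templates,
        spike_trains=spike_trains,
        channel_depths_um=depths,
        boundaries=boundaries,
        trials=trials,
        ground_truth=truth,
        provenance=provenance,
    )
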