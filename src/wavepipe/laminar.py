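"""Laminar depth scaling, layer assignment, and enrichment inference.

Layer boundaries come from current-source-density + histology tables and are
an input, never computed here.  Depths from different sessions are made
comparable by mapping each session's layer intervals piecewise-linearly onto
the across-session average intervals; layer membership is preserved exactly.

Layers are half-open intervals [top, bottom) with depth increasing downward;
units below the deepest gray-matter boundary fall in white matter (WM).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Sequence, Tuple

import numpy as np

from .stats import ShuffleResult, shuffle_test

__all__ = [
    "LayerModel",
    "average_boundaries",
    "scale_depth",
    "assign_layer",
    "enrichment_shuffle_test",
    "median_metric_shuffle_test",
    "distance_from_layer",
]

DEFAULT_LAYER_NAMES = ("L2/3", "L4a/4b", "L4c", "L5/6", "WM")


@dataclass
class LayerModel:
    """Ordered gray-matter layers with per-session boundary depths.

    ``session_edges[sid]`` holds the top depth (um) of every named layer;
    the last name is WM, open-ended below its top edge.  ``average_edges``
    is the elementwise mean across sessions.
    """

    layer_names: Tuple[str, ...]
    session_edges: Dict[str, np.ndarray]
    average_edges: np.ndarray

    @classmethod
    def from_sessions(cls, session_edges: Dict[str, Sequence[float]],
                      layer_names: Tuple[str, ...] = DEFAULT_LAYER_NAMES) -> "LayerModel":
        edges = {k: np.asarray(v, dtype=float) for k, v in session_edges.items()}
        for sid, e in edges.items():
            if e.size != len(layer_names):
                raise ValueError(f"session {sid}: need one top edge per layer")
            if np.any(np.diff(e) <= 0):
                raise ValueError(f"session {sid}: boundaries must strictly increase")
        return cls(tuple(layer_names), edges, average_boundaries(list(edges.values())))


def average_boundaries(session_boundaries: Sequence[Sequence[float]]) -> np.ndarray:
    """Elementwise mean of per-session boundary depths (must stay increasing)."""
    arr = np.asarray(session_boundaries, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.shape[0] < 1:
        raise ValueError("need at least one session")
    avg = arr.mean(axis=0)
    if np.any(np.diff(avg) <= 0):
        raise ValueError("averaged boundaries cross: malformed input")
    return avg


def scale_depth(
    depth_um: float,
    session_edges: Sequence[float],
    average_edges: Sequence[float],
) -> float:
    """Map a session depth into average-boundary coordinates.

    Piecewise-linear: each session layer interval maps affinely onto the
    corresponding average interval, so boundary depths map to boundary
    depths and layer membership is preserved exactly.  Depths below the WM
    top edge are shifted rigidly; depths above the first boundary are
    rejected.
    """
    s = np.asarray(session_edges, dtype=float)
    a = np.asarray(average_edges, dtype=float)
    if s.size != a.size:
        raise ValueError("edge arrays must align")
    d = float(depth_um)
    if d < s[0]:
        raise ValueError(f"depth {d} um above the covered span (top {s[0]} um)")
    if d >= s[-1]:  # white matter: rigid shift from the WM top edge
        return float(a[-1] + (d - s[-1]))
    i = int(np.searchsorted(s, d, side="right") - 1)
    frac = (d - s[i]) / (s[i + 1] - s[i])
    return float(a[i] + frac * (a[i + 1] - a[i]))


def assign_layer(scaled_depth_um: float, model: LayerModel) -> str:
    """Layer label of the half-open interval [top, bottom) containing depth."""
    e = model.average_edges
    d = float(scaled_depth_um)
    if d < e[0]:
        raise ValueError(f"depth {d} um above the first layer boundary")
    i = int(np.searchsorted(e, d, side="right") - 1)
    return model.layer_names[i]


def enrichment_shuffle_test(
    cluster_labels: Sequence,
    layers: Sequence,
    cluster,
    target_layers: Sequence[str],
    n_shuffles: int = 1000,
    seed=None,
) -> ShuffleResult:
    """Is a cluster over/under-represented in the target layers?

    Observed statistic: fraction of the cluster's units whose layer is in
    ``target_layers``.  The null permutes layer labels over units (totals
    per layer preserved); flags use the 1st/99th percentiles, so the
    attained two-sided floor is 2/n_shuffles.
    """
    cluster_labels = np.asarray(cluster_labels)
    layers = np.asarray(layers)
    in_cluster = cluster_labels == cluster
    if not np.any(in_cluster):
        raise ValueError(f"cluster {cluster!r} is empty: statistic undefined")
    targets = set(target_layers)

    def frac_in_target(_, permuted_layers):
        return np.mean(np.isin(permuted_layers[in_cluster], list(targets)))

    return shuffle_test(frac_in_target, None, layers, n_shuffles=n_shuffles, seed=seed)


def median_metric_shuffle_test(
    values: Sequence[float],
    group_labels: Sequence,
    group,
    n_shuffles: int = 1000,
    seed=None,
) -> ShuffleResult:
    """Is a group's median of a per-unit metric extreme under label exchange?

    The heat-table companion of :func:`enrichment_shuffle_test`: the observed
    statistic is the median of ``values`` within ``group`` (a cluster, a
    layer, or a layer x cluster cell id); the null permutes group labels
    over units.
    """
    values = np.asarray(values, dtype=float)
    group_labels = np.asarray(group_labels)
    if not np.any(group_labels == group):
        raise ValueError(f"group {group!r} is empty: statistic undefined")

    def group_median(vals, permuted):
        return float(np.median(vals[permuted == group]))

    return shuffle_test(group_median, values, group_labels,
                        n_shuffles=n_shuffles, seed=seed)


def distance_from_layer(
    scaled_depths_um: Sequence[float],
    model: LayerModel,
    reference_layer: str,
) -> Tuple[float, Tuple[float, float]]:
    """Mean distance (um) of units from a reference layer, with normal 95% CI.

    Distance is 0 inside the layer, else the gap to its nearest edge.
    """
    if reference_layer not in model.layer_names:
        raise ValueError(f"unknown layer {reference_layer!r}")
    depths = np.asarray(scaled_depths_um, dtype=float)
    if depths.size == 0:
        raise ValueError("no units supplied")
    i = model.layer_names.index(reference_layer)
    top = model.average_edges[i]
    bottom = (
        model.average_edges[i + 1] if i + 1 < len(model.average_edges) else np.inf
    )
    dist = np.where(
        depths < top, top - depths, np.where(depths >= bottom, depths - bottom, 0.0)
    )
    mean = float(dist.mean())
    if depths.size > 1:
        half = 1.96 * dist.std(ddof=1) / np.sqrt(dist.size)
    else:
        half = 0.0
    return mean, (mean - half, mean + half)
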