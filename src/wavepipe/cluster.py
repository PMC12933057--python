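"""Candidate cell-type discovery from normalized waveforms.

Nonlinear embedding (UMAP) of the normalized somatic waveforms builds a
high-dimensional fuzzy neighbor graph; Louvain-style community detection
(Leiden refinement of modularity with a resolution parameter) on that graph
— not on the 2-D layout — yields the candidate cell-type labels.  Three
validation analyses accompany the clustering: a resolution sweep over data
subsamples, a cross-validated gradient-boosted-tree classifier confusion
matrix, and an ensemble-clustering consensus with an adjusted-Rand
agreement score.  A variance-decomposition utility asks how much of the
units' functional properties the embedding and labels explain beyond depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Tuple

import igraph as ig
import leidenalg as la
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.ensemble import HistGradientBoostingClassifier
from sklearn.metrics import adjusted_rand_score
from sklearn.model_selection import StratifiedKFold, cross_val_predict

from .stats import as_rng

__all__ = [
    "ClusterResult",
    "SweepResult",
    "embed_and_graph",
    "louvain",
    "modularity",
    "wavemap",
    "resolution_sweep",
    "classifier_validation",
    "agreement_score",
    "ecg_compare",
    "variance_decomposition",
    "name_clusters",
]

DEFAULT_N_NEIGHBORS = 20
DEFAULT_MIN_DIST = 0.2
DEFAULT_RESOLUTION = 1.0


@dataclass
class ClusterResult:
    embedding_2d: np.ndarray
    neighbor_graph: sp.csr_matrix
    labels: np.ndarray
    modularity_q: float
    resolution: float
    params: dict = field(default_factory=dict)


@dataclass
class SweepResult:
    resolutions: np.ndarray
    mean_modularity: np.ndarray
    sd_modularity: np.ndarray
    mean_n_clusters: np.ndarray
    sd_n_clusters: np.ndarray
    n_subsamples: int
    subsample_fraction: float
    recommended_resolution: float


def embed_and_graph(
    waveforms,
    n_neighbors: int = DEFAULT_N_NEIGHBORS,
    min_dist: float = DEFAULT_MIN_DIST,
    seed: int = 0,
) -> Tuple[np.ndarray, sp.csr_matrix]:
    """UMAP 2-D embedding plus the high-dimensional fuzzy neighbor graph.

    The returned graph is the symmetric weighted fuzzy simplicial set UMAP
    optimizes its layout from; community detection operates on it directly.
    """
    import umap  # deferred: numba compilation is expensive at import

    X = np.asarray(waveforms, dtype=float)
    if X.ndim != 2:
        raise ValueError("waveforms must be a 2-D array (units x samples)")
    if X.shape[0] <= n_neighbors:
        raise ValueError(
            f"need more than n_neighbors={n_neighbors} units, got {X.shape[0]}"
        )
    reducer = umap.UMAP(
        n_neighbors=n_neighbors, min_dist=min_dist, n_components=2, random_state=seed
    )
    embedding = reducer.fit_transform(X)
    graph = sp.csr_matrix(reducer.graph_)
    graph = graph.maximum(graph.T)  # enforce symmetry
    return np.asarray(embedding), graph


def _to_igraph(graph: sp.spmatrix) -> ig.Graph:
    coo = sp.triu(sp.csr_matrix(graph), k=1).tocoo()
    g = ig.Graph(
        n=graph.shape[0], edges=list(zip(coo.row.tolist(), coo.col.tolist()))
    )
    g.es["weight"] = coo.data.tolist()
    return g


def modularity(graph: sp.spmatrix, labels, resolution: float = 1.0) -> float:
    """Newman modularity of a partition on a weighted undirected graph.

    Direct formula Q = sum_c [ w_in_c / W - gamma (k_c / 2W)^2 ] with W the
    total edge weight; written independently of the community-detection
    library so the two can be cross-checked.
    """
    A = sp.csr_matrix(graph).astype(np.float64)
    labels = np.asarray(labels)
    two_w = A.sum()
    if two_w == 0:
        raise ValueError("empty graph")
    degrees = np.asarray(A.sum(axis=1)).ravel()
    q = 0.0
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        sub = A[np.ix_(idx, idx)]
        w_in = sub.sum()  # counts both triangle halves
        k_c = degrees[idx].sum()
        q += w_in / two_w - resolution * (k_c / two_w) ** 2
    return float(q)


def louvain(
    graph: sp.spmatrix,
    resolution: float = DEFAULT_RESOLUTION,
    seed: int = 0,
) -> Tuple[np.ndarray, float]:
    """Modularity-maximizing community labels at the given resolution.

    Returns ``(labels, modularity_q)`` where the reported modularity is the
    standard (resolution-1) Newman modularity of the returned partition,
    recomputed from the graph by :func:`modularity`.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    A = sp.csr_matrix(graph)
    if A.shape[0] == 0:
        raise ValueError("empty graph")
    g = _to_igraph(A)
    part = la.find_partition(
        g,
        la.RBConfigurationVertexPartition,
        weights="weight" if g.ecount() else None,
        resolution_parameter=resolution,
        seed=int(seed),
        n_iterations=-1,
    )
    labels = np.asarray(part.membership)
    return labels, modularity(A, labels)


def wavemap(
    waveforms,
    n_neighbors: int = DEFAULT_N_NEIGHBORS,
    min_dist: float = DEFAULT_MIN_DIST,
    resolution: float = DEFAULT_RESOLUTION,
    seed: int = 0,
) -> ClusterResult:
    """Embedding + neighbor graph + community detection in one call."""
    embedding, graph = embed_and_graph(waveforms, n_neighbors, min_dist, seed)
    labels, q = louvain(graph, resolution, seed)
    return ClusterResult(
        embedding_2d=embedding,
        neighbor_graph=graph,
        labels=labels,
        modularity_q=q,
        resolution=resolution,
        params=dict(n_neighbors=n_neighbors, min_dist=min_dist, seed=seed),
    )


def resolution_sweep(
    waveforms,
    grid=None,
    n_subsamples: int = 25,
    fraction: float = 0.8,
    n_neighbors: int = DEFAULT_N_NEIGHBORS,
    min_dist: float = DEFAULT_MIN_DIST,
    seed: int = 0,
) -> SweepResult:
    """Stability of modularity and cluster count over a resolution grid.

    Each of ``n_subsamples`` random subsamples (``fraction`` of the units)
    is embedded once; community detection runs at every grid resolution on
    its graph.  The recommended resolution maximizes mean modularity.
    """
    X = np.asarray(waveforms, dtype=float)
    if grid is None:
        grid = np.arange(0.5, 10.01, 0.5)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("resolution grid must be nonempty")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    rng = as_rng(seed)
    n_take = max(n_neighbors + 1, int(round(fraction * X.shape[0])))
    q = np.empty((n_subsamples, grid.size))
    k = np.empty((n_subsamples, grid.size))
    for s in range(n_subsamples):
        idx = (
            np.arange(X.shape[0])
            if n_take >= X.shape[0]
            else rng.choice(X.shape[0], size=n_take, replace=False)
        )
        _, graph = embed_and_graph(X[idx], n_neighbors, min_dist, seed=seed + s)
        for j, res in enumerate(grid):
            labels, qj = louvain(graph, res, seed=seed + s)
            q[s, j] = qj
            k[s, j] = np.unique(labels).size
    mean_q = q.mean(axis=0)
    return SweepResult(
        resolutions=grid,
        mean_modularity=mean_q,
        sd_modularity=q.std(axis=0, ddof=0),
        mean_n_clusters=k.mean(axis=0),
        sd_n_clusters=k.std(axis=0, ddof=0),
        n_subsamples=n_subsamples,
        subsample_fraction=fraction,
        recommended_resolution=float(grid[int(np.argmax(mean_q))]),
    )


def classifier_validation(
    waveforms,
    labels,
    n_folds: int = 5,
    seed: int = 0,
) -> Tuple[np.ndarray, float]:
    """Cross-validated gradient-boosted-tree readout of the cluster labels.

    Returns the row-normalized confusion matrix (rows = true clusters,
    summing to 1) and the mean of its diagonal (average per-cluster
    accuracy).  Every cluster must have at least ``n_folds`` members.
    """
    X = np.asarray(waveforms, dtype=float)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    small = classes[counts < n_folds]
    if small.size:
        raise ValueError(f"clusters smaller than n_folds={n_folds}: {small.tolist()}")
    clf = HistGradientBoostingClassifier(max_depth=3, random_state=seed)
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    pred = cross_val_predict(clf, X, y, cv=cv)
    K = classes.size
    cm = np.zeros((K, K))
    index = {c: i for i, c in enumerate(classes)}
    for t, p in zip(y, pred):
        cm[index[t], index[p]] += 1
    cm = cm / cm.sum(axis=1, keepdims=True)
    return cm, float(np.mean(np.diag(cm)))


def agreement_score(labels_a, labels_b) -> float:
    """Chance-corrected partition agreement (adjusted Rand index, in [-1, 1])."""
    return float(adjusted_rand_score(np.asarray(labels_a), np.asarray(labels_b)))


def ecg_compare(
    graph: sp.spmatrix,
    labels_louvain,
    n_ensemble: int = 20,
    seed: int = 0,
) -> Tuple[np.ndarray, float]:
    """Ensemble-of-partitions consensus clustering and agreement score.

    Runs community detection ``n_ensemble`` times with different seeds,
    reweights each graph edge by the fraction of runs in which its endpoints
    share a community, and partitions the reweighted graph (resolution 1).
    Agreement with the reference labels is the adjusted Rand index in
    [-1, 1].
    """
    A = sp.csr_matrix(graph)
    coo = sp.triu(A, k=1).tocoo()
    co = np.zeros(coo.nnz)
    for i in range(n_ensemble):
        member, _ = louvain(A, DEFAULT_RESOLUTION, seed=seed + 1 + i)
        co += member[coo.row] == member[coo.col]
    co /= n_ensemble
    consensus = sp.coo_matrix(
        (np.maximum(co, 0.05), (coo.row, coo.col)), shape=A.shape
    ).tocsr()
    consensus = consensus.maximum(consensus.T)
    ecg_labels, _ = louvain(consensus, DEFAULT_RESOLUTION, seed=seed)
    return ecg_labels, agreement_score(labels_louvain, ecg_labels)


def _adjusted_r2(y: np.ndarray, X: np.ndarray) -> float:
    import statsmodels.api as sm

    model = sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()
    return float(model.rsquared_adj)


def variance_decomposition(
    units: pd.DataFrame,
    functional_table: pd.DataFrame,
    depth_col: str = "depth_um",
    embedding_cols: Sequence[str] = ("embedding_x", "embedding_y"),
    cluster_col: str = "cluster",
    snr_col: str = "snr",
) -> pd.DataFrame:
    """Adjusted R-squared of functional properties under nested models.

    Models: depth alone, depth + 2-D embedding, depth + cluster (one-hot),
    and SNR alone; fitted per functional column and pooled (mean across
    columns).  Constant responses are flagged and reported as 0.
    """
    if len(units) != len(functional_table):
        raise ValueError("units and functional_table must align row-wise")
    depth = units[[depth_col]].to_numpy(dtype=float)
    emb = units[list(embedding_cols)].to_numpy(dtype=float)
    onehot = pd.get_dummies(units[cluster_col], drop_first=True).to_numpy(dtype=float)
    snr = units[[snr_col]].to_numpy(dtype=float)
    designs = {
        "depth": depth,
        "depth+embedding": np.hstack([depth, emb]),
        "depth+cluster": np.hstack([depth, onehot]),
        "snr": snr,
    }
    rows = {}
    for col in functional_table.columns:
        y = functional_table[col].to_numpy(dtype=float)
        ok = np.isfinite(y)
        rows[col] = {}
        for name, X in designs.items():
            if np.ptp(y[ok]) == 0:
                rows[col][name] = 0.0  # constant response: flagged as no variance
            else:
                rows[col][name] = _adjusted_r2(y[ok], X[ok])
    out = pd.DataFrame(rows).T
    out.loc["pooled"] = out.mean(axis=0)
    return out


def name_clusters(
    labels,
    durations_ms,
    n_phases=None,
    narrow_cut_ms: float = 0.35,
) -> dict:
    """Field-style cluster names from trough-to-peak duration ranks.

    Clusters with a triphasic majority are TP-k; the rest split into
    narrow-spiking (NS-k, median duration < ``narrow_cut_ms``) and
    broad-spiking (BS-k), numbered by increasing duration.
    """
    labels = np.asarray(labels)
    durations_ms = np.asarray(durations_ms, dtype=float)
    groups = []
    for c in np.unique(labels):
        m = labels == c
        med = np.nanmedian(durations_ms[m])
        tri = (
            n_phases is not None
            and np.mean(np.asarray(n_phases)[m] == 3) > 0.5
        )
        groups.append((c, med, tri))
    names = {}
    for prefix, sel in (
        ("TP", [g for g in groups if g[2]]),
        ("NS", [g for g in groups if not g[2] and g[1] < narrow_cut_ms]),
        ("BS", [g for g in groups if not g[2] and g[1] >= narrow_cut_ms]),
    ):
        for rank, (c, _, _) in enumerate(sorted(sel, key=lambda g: g[1]), start=1):
            names[c] = f"{prefix}-{rank}"
    return names
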