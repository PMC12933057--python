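"""Embedding graph, community detection, and the validation analyses."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from wavepipe import cluster as cl


def _clique_graph(sizes, inter_weight=0.0):
    """Block-diagonal union of cliques, optionally weakly interconnected."""
    n = sum(sizes)
    A = np.full((n, n), inter_weight)
    start = 0
    for s in sizes:
        A[start:start + s, start:start + s] = 1.0
        start += s
    np.fill_diagonal(A, 0.0)
    return sp.csr_matrix(A)


def _brute_force_ari(a, b):
    """Adjusted Rand from the contingency table (independent oracle)."""
    from math import comb

    a = np.asarray(a)
    b = np.asarray(b)
    n = a.size
    sum_ij = sum(
        comb(np.sum((a == ca) & (b == cb)), 2)
        for ca in np.unique(a)
        for cb in np.unique(b)
    )
    sum_a = sum(comb(np.sum(a == ca), 2) for ca in np.unique(a))
    sum_b = sum(comb(np.sum(b == cb), 2) for cb in np.unique(b))
    expected = sum_a * sum_b / comb(n, 2)
    max_idx = (sum_a + sum_b) / 2
    if max_idx == expected:
        return 1.0
    return (sum_ij - expected) / (max_idx - expected)


class TestEmbedAndGraph:
    def test_duplicate_unit_gets_maximal_edge_weight(self, shape_families):
        W, _ = shape_families
        X = np.vstack([W[:40], W[0]])  # last row duplicates row 0
        _, graph = cl.embed_and_graph(X, n_neighbors=10, seed=0)
        assert graph[40, 0] == pytest.approx(1.0)

    def test_separated_families_have_weak_inter_family_weight(self, shape_families):
        W, labels = shape_families
        _, graph = cl.embed_and_graph(W, n_neighbors=10, seed=0)
        same = labels[:, None] == labels[None, :]
        dense = graph.toarray()
        intra = dense[same].sum()
        inter = dense[~same].sum()
        assert inter < 0.05 * intra

    def test_same_seed_identical_embedding(self, shape_families):
        W, _ = shape_families
        e1, _ = cl.embed_and_graph(W[:40], n_neighbors=10, seed=3)
        e2, _ = cl.embed_and_graph(W[:40], n_neighbors=10, seed=3)
        np.testing.assert_array_equal(e1, e2)

    def test_too_few_units_rejected(self):
        with pytest.raises(ValueError):
            cl.embed_and_graph(np.zeros((5, 54)), n_neighbors=20)


class TestLouvain:
    def test_two_disconnected_cliques_found(self):
        labels, q = cl.louvain(_clique_graph([10, 10]), resolution=1.0, seed=0)
        assert np.unique(labels).size == 2
        assert np.unique(labels[:10]).size == 1 and np.unique(labels[10:]).size == 1

    def test_single_clique_single_community(self):
        labels, _ = cl.louvain(_clique_graph([12]), resolution=1.0, seed=0)
        assert np.unique(labels).size == 1

    def test_modularity_matches_networkx(self, shape_families):
        import networkx as nx

        W, _ = shape_families
        _, graph = cl.embed_and_graph(W, n_neighbors=10, seed=0)
        labels, q = cl.louvain(graph, seed=0)
        G = nx.from_scipy_sparse_array(sp.csr_matrix(graph).astype(np.float64))
        comms = [set(np.flatnonzero(labels == c)) for c in np.unique(labels)]
        assert q == pytest.approx(nx.community.modularity(G, comms, weight="weight"),
                                  abs=1e-9)

    def test_nonpositive_resolution_rejected(self):
        with pytest.raises(ValueError):
            cl.louvain(_clique_graph([5]), resolution=0.0)

    def test_labels_permutation_equivariant_on_cliques(self):
        A = _clique_graph([8, 8, 8])
        labels, _ = cl.louvain(A, seed=1)
        perm = np.random.default_rng(2).permutation(24)
        Ap = A[perm][:, perm]
        labels_p, _ = cl.louvain(sp.csr_matrix(Ap), seed=1)
        assert cl.agreement_score(labels_p, labels[perm]) == 1.0


class TestResolutionSweep:
    def test_single_full_subsample_has_zero_sds(self, shape_families):
        W, _ = shape_families
        res = cl.resolution_sweep(W, grid=[0.5, 1.0], n_subsamples=1, fraction=1.0,
                                  n_neighbors=10, seed=0)
        assert np.all(res.sd_modularity == 0.0)
        assert np.all(res.sd_n_clusters == 0.0)

    def test_cluster_count_grows_and_recommended_recovers_three(self, shape_families):
        W, _ = shape_families
        res = cl.resolution_sweep(W, grid=[0.5, 1.0, 2.0, 4.0, 8.0], n_subsamples=3,
                                  fraction=0.8, n_neighbors=20, seed=0)
        assert np.all(np.diff(res.mean_n_clusters) >= 0)
        labels, _ = cl.louvain(
            cl.embed_and_graph(W, n_neighbors=20, seed=0)[1],
            res.recommended_resolution, seed=0,
        )
        assert np.unique(labels).size == 3

    def test_bad_fraction_rejected(self, shape_families):
        with pytest.raises(ValueError):
            cl.resolution_sweep(shape_families[0], grid=[1.0], fraction=1.5)


class TestClassifierValidation:
    def test_confusion_rows_sum_to_one(self, shape_families):
        W, labels = shape_families
        cm, _ = cl.classifier_validation(W, labels, seed=0)
        np.testing.assert_allclose(cm.sum(axis=1), 1.0, atol=1e-9)

    def test_separated_families_classified_accurately(self, shape_families):
        W, labels = shape_families
        _, acc = cl.classifier_validation(W, labels, seed=0)
        assert acc >= 0.95

    def test_shuffled_labels_at_chance(self, shape_families):
        W, labels = shape_families
        rng = np.random.default_rng(1)
        _, acc = cl.classifier_validation(W, rng.permutation(labels), seed=0)
        k = np.unique(labels).size
        se = np.sqrt((1 / k) * (1 - 1 / k) / labels.size)
        assert abs(acc - 1 / k) < 3 * se + 0.05

    def test_small_class_rejected_by_name(self, shape_families):
        W, labels = shape_families
        labels = labels.copy()
        labels[:2] = "rare"
        with pytest.raises(ValueError, match="rare"):
            cl.classifier_validation(W, labels)


class TestAgreement:
    def test_identical_partitions_score_one_exactly(self):
        labels = np.repeat([0, 1, 2], 10)
        assert cl.agreement_score(labels, labels) == 1.0

    def test_all_in_one_vs_balanced_is_chance(self):
        a = np.zeros(30, dtype=int)
        b = np.repeat([0, 1, 2], 10)
        assert cl.agreement_score(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_contingency_formula(self, rng):
        for _ in range(20):
            a = rng.integers(0, 4, size=50)
            b = rng.integers(0, 3, size=50)
            assert cl.agreement_score(a, b) == pytest.approx(
                _brute_force_ari(a, b), abs=1e-12
            )

    def test_ecg_consensus_agrees_on_separated_families(self, shape_families):
        W, _ = shape_families
        _, graph = cl.embed_and_graph(W, n_neighbors=10, seed=0)
        labels, _ = cl.louvain(graph, seed=0)
        ecg_labels, score = cl.ecg_compare(graph, labels, n_ensemble=10, seed=0)
        assert score > 0.8


class TestVarianceDecomposition:
    def _units(self, n, rng):
        return pd.DataFrame(
            dict(
                depth_um=rng.uniform(0, 1500, n),
                embedding_x=rng.normal(size=n),
                embedding_y=rng.normal(size=n),
                cluster=rng.integers(0, 4, size=n),
                snr=rng.uniform(3, 30, n),
            )
        )

    def test_pure_noise_explains_nothing(self, rng):
        units = self._units(300, rng)
        func = pd.DataFrame(dict(osi=rng.normal(size=300)))
        out = cl.variance_decomposition(units, func)
        assert np.all(np.abs(out.loc["osi"]) < 0.05)

    def test_linear_depth_response_fully_explained(self, rng):
        units = self._units(200, rng)
        func = pd.DataFrame(dict(y=0.01 * units.depth_um - 3.0))
        out = cl.variance_decomposition(units, func)
        assert out.loc["y", "depth"] >= 0.99

    def test_useless_predictor_does_not_raise_adjusted_r2(self, rng):
        # over replicates, adding noise dimensions should not help on average
        diffs = []
        for _ in range(100):
            units = self._units(60, rng)
            func = pd.DataFrame(dict(y=rng.normal(size=60)))
            out = cl.variance_decomposition(units, func)
            diffs.append(out.loc["y", "depth+embedding"] - out.loc["y", "depth"])
        assert np.mean(diffs) < 0.01

    def test_constant_response_reported_as_zero(self, rng):
        units = self._units(50, rng)
        func = pd.DataFrame(dict(y=np.ones(50)))
        out = cl.variance_decomposition(units, func)
        assert np.all(out.loc["y"] == 0.0)


class TestClusterNaming:
    def test_names_follow_duration_rank_and_phases(self):
        labels = np.repeat([0, 1, 2, 3], 5)
        durations = np.repeat([0.5, 0.2, 0.3, 0.7], 5)
        phases = np.repeat([2, 2, 3, 2], 5)
        names = cl.name_clusters(labels, durations, phases)
        assert names == {1: "NS-1", 2: "TP-1", 0: "BS-1", 3: "BS-2"}
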