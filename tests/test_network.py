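"""EBIC-glasso networks: closed forms, support recovery, centralities."""

from __future__ import annotations

import networkx  # noqa: F401  (oracle below deliberately avoids networkx)
import numpy as np
import pandas as pd
import pytest
from sklearn.covariance import graphical_lasso

from speechsyntax.network import (
    NetworkModel,
    bootstrap_edges,
    centralities,
    estimate_ggm,
    fr_layout,
    partial_correlations_from_precision,
)


def model_from_weights(w, labels=None):
    w = np.asarray(w, dtype=float)
    labels = tuple(labels or (f"n{i}" for i in range(len(w))))
    return NetworkModel(
        node_labels=labels, weights=w, precision=np.eye(len(w)),
        lambda_path=np.array([1.0]), ebic_by_lambda=np.array([0.0]),
        lambda_selected=1.0, gamma=0.25, sample_size=100,
    )


def planted_precision(p=11, n_edges=8, pc=0.3, seed=0):
    """Sparse precision with unit diagonal and max node degree 2 (hence PD)."""
    rng = np.random.default_rng(seed)
    K = np.eye(p)
    edges = []
    degree = np.zeros(p, dtype=int)
    while len(edges) < n_edges:
        i, j = sorted(rng.choice(p, 2, replace=False))
        if (i, j) in edges or degree[i] >= 2 or degree[j] >= 2:
            continue
        edges.append((i, j))
        degree[i] += 1
        degree[j] += 1
        K[i, j] = K[j, i] = -pc
    assert np.linalg.eigvalsh(K).min() > 0
    return K, set(edges)


class TestEstimation:
    def test_closed_form_three_node_partial_correlations(self):
        K = np.array([[2.0, 1, 0], [1, 2, 1], [0, 1, 2]])
        w = partial_correlations_from_precision(K)
        assert w[0, 1] == pytest.approx(-0.5)
        assert w[0, 2] == pytest.approx(0.0)
        assert w[1, 2] == pytest.approx(-0.5)
        assert np.allclose(np.diag(w), 0)

    def test_weights_are_symmetric_bounded_with_zero_diagonal(self):
        rng = np.random.default_rng(1)
        X = rng.multivariate_normal(np.zeros(5), np.eye(5) + 0.4, size=80)
        model = estimate_ggm(X, n_lambda=40)
        assert np.allclose(model.weights, model.weights.T, atol=1e-10)
        assert np.all(np.diag(model.weights) == 0)
        assert np.max(np.abs(model.weights)) <= 1

    def test_largest_lambda_of_the_path_gives_the_empty_network(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(60, 6))
        model = estimate_ggm(X, n_lambda=30)
        _, theta = graphical_lasso(np.corrcoef(X, rowvar=False),
                                   alpha=float(model.lambda_path[0]))
        w = partial_correlations_from_precision(theta)
        assert np.allclose(w, 0, atol=1e-8)

    def test_independent_data_give_near_empty_networks(self):
        hits = 0
        for seed in range(10):
            X = np.random.default_rng(seed).normal(size=(500, 11))
            model = estimate_ggm(X, gamma=0.25, n_lambda=50)
            hits += model.n_edges <= 2
        assert hits >= 9

    def test_planted_sparse_support_is_recovered(self):
        recalls, false_counts = [], []
        for seed in range(3):
            K, edges = planted_precision(seed=seed)
            cov = np.linalg.inv(K)
            X = np.random.default_rng(100 + seed).multivariate_normal(
                np.zeros(11), cov, size=500
            )
            model = estimate_ggm(X, gamma=0.25)
            found = {
                (i, j)
                for i in range(11)
                for j in range(i + 1, 11)
                if abs(model.weights[i, j]) > 1e-8
            }
            recalls.append(len(found & edges) / len(edges))
            false_counts.append(len(found - edges))
        assert min(recalls) >= 0.8
        assert np.mean(false_counts) <= 2

    def test_gamma_zero_reduces_to_bic_and_higher_gamma_is_never_denser(self):
        rng = np.random.default_rng(3)
        K, _ = planted_precision(seed=5)
        X = rng.multivariate_normal(np.zeros(11), np.linalg.inv(K), size=120)
        m0 = estimate_ggm(X, gamma=0.0, n_lambda=50)
        m5 = estimate_ggm(X, gamma=0.5, n_lambda=50)
        assert m5.n_edges <= m0.n_edges
        # with gamma = 0 the EBIC curve is the BIC curve; the selected lambda
        # is its argmin
        assert m0.lambda_selected == m0.lambda_path[int(np.argmin(m0.ebic_by_lambda))]

    def test_preconditions(self):
        rng = np.random.default_rng(4)
        with pytest.raises(ValueError, match="n >= 20"):
            estimate_ggm(rng.normal(size=(10, 5)))
        X = rng.normal(size=(40, 4))
        X[:, 2] = 1.0
        with pytest.raises(ValueError, match="constant"):
            estimate_ggm(X)


class TestCentralities:
    def test_hand_computed_path_graph(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.5
        w[1, 2] = w[2, 1] = -0.3
        rep = centralities(model_from_weights(w, ["a", "b", "c"])).set_index("node")
        assert rep.loc["b", "strength"] == pytest.approx(0.8)
        assert rep.loc["b", "expected_influence"] == pytest.approx(0.2)
        assert rep.loc["b", "betweenness"] == pytest.approx(1.0)
        # d(a,b) = 2, d(a,c) = 2 + 10/3
        assert rep.loc["a", "closeness"] == pytest.approx(1.0 / (2 + 2 + 10 / 3))

    def test_disconnected_network_has_zero_centralities(self):
        rep = centralities(model_from_weights(np.zeros((4, 4))))
        assert (rep[["strength", "expected_influence", "closeness", "betweenness"]] == 0).all().all()

    def test_expected_influence_never_exceeds_strength(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            w = rng.uniform(-0.5, 0.5, size=(6, 6))
            w = (w + w.T) / 2
            np.fill_diagonal(w, 0)
            w[np.abs(w) < 0.2] = 0
            rep = centralities(model_from_weights(w))
            assert (rep["expected_influence"] <= rep["strength"] + 1e-12).all()

    def test_matches_brute_force_shortest_path_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(15):
            p = int(rng.integers(3, 7))
            w = rng.uniform(-0.8, 0.8, size=(p, p))
            w = (w + w.T) / 2
            np.fill_diagonal(w, 0)
            w[np.abs(w) < 0.3] = 0
            rep = centralities(model_from_weights(w)).set_index("node")

            # Floyd-Warshall on lengths 1/|w|, with path counting
            INF = np.inf
            dist = np.full((p, p), INF)
            np.fill_diagonal(dist, 0)
            for i in range(p):
                for j in range(p):
                    if i != j and w[i, j] != 0:
                        dist[i, j] = 1 / abs(w[i, j])
            for k in range(p):
                for i in range(p):
                    for j in range(p):
                        alt = dist[i, k] + dist[k, j]
                        if alt < dist[i, j]:
                            dist[i, j] = alt

            # betweenness: fraction of shortest paths through each node.
            # random continuous weights make ties measure-zero, so each pair
            # has a unique shortest path and the count is 0/1 per node.
            for v in range(p):
                btw = 0.0
                for i in range(p):
                    for j in range(i + 1, p):
                        if i == v or j == v or dist[i, j] == INF:
                            continue
                        via = dist[i, v] + dist[v, j]
                        if abs(via - dist[i, j]) <= 1e-9:
                            btw += 1.0
                assert rep.iloc[v]["betweenness"] == pytest.approx(btw), "betweenness"
                reach = [j for j in range(p) if j != v and dist[v, j] < INF]
                if reach:
                    expected = (len(reach) / (p - 1)) * (1 / sum(dist[v, j] for j in reach))
                else:
                    expected = 0.0
                assert rep.iloc[v]["closeness"] == pytest.approx(expected), "closeness"
                assert rep.iloc[v]["strength"] == pytest.approx(np.abs(w[v]).sum())
                assert rep.iloc[v]["expected_influence"] == pytest.approx(w[v].sum())


class TestBootstrap:
    def test_single_resample_collapses_the_quantiles(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(60, 4))
        boot = bootstrap_edges(X, B=1, seed=0, n_lambda=25)
        assert np.allclose(boot["q025"], boot["q50"])
        assert np.allclose(boot["q50"], boot["q975"])

    def test_strong_planted_edge_is_stable_and_null_edges_are_not(self):
        rng = np.random.default_rng(8)
        K = np.eye(6)
        K[0, 1] = K[1, 0] = -0.6
        X = rng.multivariate_normal(np.zeros(6), np.linalg.inv(K), size=200)
        boot = bootstrap_edges(X, B=60, seed=1, n_lambda=30)
        planted = boot[(boot.node_i == "v0") & (boot.node_j == "v1")]
        assert planted["nonzero_freq"].iloc[0] > 0.95
        null = rng.normal(size=(200, 6))
        boot_null = bootstrap_edges(null, B=60, seed=2, n_lambda=30)
        assert boot_null["nonzero_freq"].median() < 0.2


class TestLayout:
    def test_single_node_sits_at_the_center(self):
        layout = fr_layout(model_from_weights(np.zeros((1, 1)), ["only"]))
        assert layout.loc[0, "x"] == 0.5 and layout.loc[0, "y"] == 0.5

    def test_fixed_seed_reproduces_coordinates(self):
        rng = np.random.default_rng(9)
        w = rng.uniform(-0.5, 0.5, size=(5, 5))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        model = model_from_weights(w)
        assert fr_layout(model, seed=4).equals(fr_layout(model, seed=4))

    def test_an_edge_pulls_two_nodes_together(self):
        w_edge = np.array([[0.0, 0.9, 0], [0.9, 0, 0], [0, 0, 0]])
        w_none = np.zeros((3, 3))
        a = fr_layout(model_from_weights(w_edge), seed=0)
        b = fr_layout(model_from_weights(w_none), seed=0)

        def dist(frame):
            return np.hypot(frame.x[0] - frame.x[1], frame.y[0] - frame.y[1])

        assert dist(a) < dist(b)
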