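"""Regularized partial-correlation networks over language-related variables.

A Gaussian graphical model is estimated from 11 variables (the five syntax
measures, four language-related neuropsychological scores and two formal
thought-disorder ratings): the Pearson correlation matrix is fed to the
graphical lasso along a log-spaced penalty path and the penalty is selected
by the Extended Bayesian Information Criterion

    EBIC(lambda) = -2 lnL + E ln n + 4 gamma E ln p,

with E the number of nonzero (upper-triangle) edges, p the number of nodes
and gamma the hyperparameter (default 0.25; gamma = 0 reduces to BIC).
Edge weights are the regularized partial correlations
``w_ij = -kappa_ij / sqrt(kappa_ii * kappa_jj)`` from the selected precision
matrix kappa.

Centralities on the weighted graph: strength (sum |w|), expected influence
(sum of signed w), and shortest-path closeness / betweenness with edge
length ``1 / |w|`` restricted to nonzero edges.  Closeness for a node in a
disconnected graph is computed within its component and scaled by the share
of other nodes it can reach.  Edge stability comes from case-resampling
bootstrap.  The +-0.1 display threshold affects rendering only; stored
weights are never thresholded.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.covariance import graphical_lasso
from sklearn.exceptions import ConvergenceWarning

logger = logging.getLogger(__name__)

#: Default node set: syntax, neuropsychology, psychopathology.
DEFAULT_NODES = (
    "relative_sum_sub",
    "extended_relative_sum_sub",
    "pure_syntactic_complexity",
    "weighted_sum_sub",
    "syntactic_diversity",
    "semantic_vf",
    "phonemic_vf",
    "alternating_vf",
    "verbal_episodic_memory",
    "neg_ftd",
    "pos_ftd",
)

DISPLAY_THRESHOLD = 0.1
_EDGE_EPS = 1e-8


@dataclass
class NetworkModel:
    node_labels: Tuple[str, ...]
    weights: np.ndarray                  # symmetric, zero diagonal
    precision: np.ndarray
    lambda_path: np.ndarray              # decreasing
    ebic_by_lambda: np.ndarray
    lambda_selected: float
    gamma: float
    sample_size: int

    @property
    def n_edges(self) -> int:
        iu = np.triu_indices_from(self.weights, k=1)
        return int((np.abs(self.weights[iu]) > _EDGE_EPS).sum())

    def edge_list(self, threshold: float = 0.0) -> pd.DataFrame:
        rows = []
        p = len(self.node_labels)
        for i in range(p):
            for j in range(i + 1, p):
                w = float(self.weights[i, j])
                if abs(w) > max(threshold, 0.0) or (threshold == 0.0 and abs(w) > _EDGE_EPS):
                    rows.append({"node_i": self.node_labels[i],
                                 "node_j": self.node_labels[j],
                                 "weight": w})
        return pd.DataFrame(rows, columns=["node_i", "node_j", "weight"])


def partial_correlations_from_precision(precision: np.ndarray) -> np.ndarray:
    """w_ij = -kappa_ij / sqrt(kappa_ii kappa_jj), zero diagonal."""
    d = np.sqrt(np.diag(precision))
    w = -precision / np.outer(d, d)
    np.fill_diagonal(w, 0.0)
    return (w + w.T) / 2.0


def _gaussian_loglik(S: np.ndarray, theta: np.ndarray, n: int) -> float:
    p = S.shape[0]
    sign, logdet = np.linalg.slogdet(theta)
    if sign <= 0:
        return -np.inf
    return 0.5 * n * (logdet - np.trace(S @ theta) - p * np.log(2 * np.pi))


def ebic(S: np.ndarray, theta: np.ndarray, n: int, gamma: float) -> float:
    p = S.shape[0]
    iu = np.triu_indices(p, k=1)
    E = int((np.abs(theta[iu]) > _EDGE_EPS).sum())
    return float(-2.0 * _gaussian_loglik(S, theta, n) + E * np.log(n) + 4.0 * gamma * E * np.log(p))


def estimate_ggm(
    data: pd.DataFrame | np.ndarray,
    gamma: float = 0.25,
    n_lambda: int = 100,
    lambda_min_ratio: float = 0.01,
    node_labels: Optional[Sequence[str]] = None,
) -> NetworkModel:
    """EBIC-selected graphical-lasso partial-correlation network.

    ``data`` is participants x variables, complete (no NaN), n >= 20.
    """
    if isinstance(data, pd.DataFrame):
        labels = tuple(data.columns)
        X = data.to_numpy(dtype=float)
    else:
        X = np.asarray(data, dtype=float)
        labels = tuple(node_labels) if node_labels is not None else tuple(
            f"v{i}" for i in range(X.shape[1])
        )
    n, p = X.shape
    if n < 20:
        raise ValueError(f"network estimation requires n >= 20 participants, got {n}")
    if np.isnan(X).any():
        raise ValueError("data contain missing values; handle upstream")
    sds = X.std(axis=0)
    if (sds == 0).any():
        bad = [labels[i] for i in np.flatnonzero(sds == 0)]
        raise ValueError(f"constant column(s) {bad}; correlations undefined")
    S = np.corrcoef(X, rowvar=False)
    eigmin = float(np.linalg.eigvalsh(S).min())
    if eigmin <= 0:
        raise ValueError(f"correlation matrix not positive definite (min eigenvalue {eigmin:g})")

    lam_max = float(np.max(np.abs(S - np.diag(np.diag(S)))))
    lambda_path = np.logspace(np.log10(lam_max), np.log10(lam_max * lambda_min_ratio), n_lambda)

    best = None
    ebics = np.full(n_lambda, np.inf)
    precisions: List[Optional[np.ndarray]] = [None] * n_lambda
    for i, lam in enumerate(lambda_path):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                _, theta = graphical_lasso(S, alpha=float(lam), max_iter=500)
        except (FloatingPointError, np.linalg.LinAlgError, ValueError) as exc:
            logger.warning("graphical lasso failed at lambda=%.4g: %s", lam, exc)
            continue
        precisions[i] = theta
        ebics[i] = ebic(S, theta, n, gamma)
    if not np.isfinite(ebics).any():
        raise RuntimeError("graphical lasso failed along the entire path")
    i_best = int(np.argmin(ebics))
    theta = precisions[i_best]
    assert theta is not None
    weights = partial_correlations_from_precision(theta)
    weights[np.abs(weights) <= _EDGE_EPS] = 0.0
    return NetworkModel(
        node_labels=labels,
        weights=weights,
        precision=theta,
        lambda_path=lambda_path,
        ebic_by_lambda=ebics,
        lambda_selected=float(lambda_path[i_best]),
        gamma=float(gamma),
        sample_size=n,
    )


def _weighted_graph(weights: np.ndarray, labels: Sequence[str]) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(labels)
    p = len(labels)
    for i in range(p):
        for j in range(i + 1, p):
            w = float(weights[i, j])
            if abs(w) > _EDGE_EPS:
                g.add_edge(labels[i], labels[j], weight=w, abs_weight=abs(w),
                           length=1.0 / abs(w))
    return g


def centralities(network: NetworkModel) -> pd.DataFrame:
    """Strength, expected influence, closeness, betweenness per node.

    Closeness of node i is ``(r_i / (n-1)) * (1 / sum of shortest-path
    distances to its r_i reachable nodes)`` with edge length 1/|w|; isolated
    nodes get 0.  Betweenness is the raw count of node-pair shortest paths
    passing through the node.
    """
    if not np.all(np.isfinite(network.weights)):
        raise ValueError("network weights must be finite")
    labels = network.node_labels
    w = network.weights
    g = _weighted_graph(w, labels)
    n = len(labels)
    strength = {lab: float(np.abs(w[i]).sum()) for i, lab in enumerate(labels)}
    ei = {lab: float(w[i].sum()) for i, lab in enumerate(labels)}
    betw = nx.betweenness_centrality(g, weight="length", normalized=False)
    closeness = {}
    for lab in labels:
        dists = nx.single_source_dijkstra_path_length(g, lab, weight="length")
        dists.pop(lab, None)
        if not dists:
            closeness[lab] = 0.0
            if g.degree(lab) == 0:
                logger.debug("node %s is isolated; closeness set to 0", lab)
        else:
            r = len(dists)
            closeness[lab] = (r / (n - 1)) * (1.0 / sum(dists.values())) if n > 1 else 0.0
    frame = pd.DataFrame(
        {
            "node": list(labels),
            "strength": [strength[x] for x in labels],
            "expected_influence": [ei[x] for x in labels],
            "closeness": [closeness[x] for x in labels],
            "betweenness": [float(betw[x]) for x in labels],
        }
    )
    for col in ("strength", "expected_influence", "closeness", "betweenness"):
        sd = frame[col].std(ddof=1)
        frame[f"{col}_z"] = (frame[col] - frame[col].mean()) / sd if sd > 0 else 0.0
    return frame


def bootstrap_edges(
    data: pd.DataFrame | np.ndarray,
    B: int = 1000,
    gamma: float = 0.25,
    seed: int = 0,
    n_lambda: int = 100,
    lambda_min_ratio: float = 0.01,
) -> pd.DataFrame:
    """Case-resampling bootstrap of edge weights.

    Per upper-triangle edge: 2.5% / 50% / 97.5% weight quantiles and the
    fraction of resamples in which the edge is nonzero.  Resamples whose
    estimation fails are dropped and counted; more than 10% failures is an
    error.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if isinstance(data, pd.DataFrame):
        labels = tuple(data.columns)
        X = data.to_numpy(dtype=float)
    else:
        X = np.asarray(data, dtype=float)
        labels = tuple(f"v{i}" for i in range(X.shape[1]))
    n, p = X.shape
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(p, k=1)
    draws = []
    failures = 0
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        try:
            model = estimate_ggm(X[idx], gamma=gamma, n_lambda=n_lambda,
                                 lambda_min_ratio=lambda_min_ratio, node_labels=labels)
        except (ValueError, RuntimeError):
            failures += 1
            continue
        draws.append(model.weights[iu])
    if failures > 0.1 * B:
        raise RuntimeError(f"{failures}/{B} bootstrap resamples failed estimation")
    if failures:
        logger.warning("%d/%d bootstrap resamples failed and were dropped", failures, B)
    W = np.asarray(draws)
    q = np.quantile(W, [0.025, 0.5, 0.975], axis=0)
    rows = []
    for e, (i, j) in enumerate(zip(*iu)):
        rows.append(
            {
                "node_i": labels[i],
                "node_j": labels[j],
                "q025": q[0, e],
                "q50": q[1, e],
                "q975": q[2, e],
                "nonzero_freq": float((np.abs(W[:, e]) > _EDGE_EPS).mean()),
            }
        )
    return pd.DataFrame(rows)


def fr_layout(
    network: NetworkModel, seed: int = 0, iterations: int = 100
) -> pd.DataFrame:
    """Fruchterman–Reingold coordinates in the unit square (|w| as attraction)."""
    labels = network.node_labels
    if len(labels) == 1:
        return pd.DataFrame({"node": list(labels), "x": [0.5], "y": [0.5]})
    g = _weighted_graph(network.weights, labels)
    pos = nx.spring_layout(g, weight="abs_weight", seed=seed, iterations=iterations)
    xy = np.array([pos[x] for x in labels], dtype=float)
    span = xy.max(axis=0) - xy.min(axis=0)
    span[span == 0] = 1.0
    xy = (xy - xy.min(axis=0)) / span
    return pd.DataFrame({"node": list(labels), "x": xy[:, 0], "y": xy[:, 1]})


def plot_network(
    network: NetworkModel,
    layout: Optional[pd.DataFrame] = None,
    threshold: float = DISPLAY_THRESHOLD,
    ax=None,
):
    """Static rendering: blue positive / red negative edges, |w| > threshold only."""
    import matplotlib.pyplot as plt

    if layout is None:
        layout = fr_layout(network)
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    pos = {r["node"]: (r["x"], r["y"]) for _, r in layout.iterrows()}
    labels = network.node_labels
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            w = network.weights[i, j]
            if abs(w) > threshold:
                xs, ys = zip(pos[labels[i]], pos[labels[j]])
                ax.plot(xs, ys, color="tab:blue" if w > 0 else "tab:red",
                        linewidth=4 * abs(w), zorder=1)
    for lab in labels:
        ax.scatter(*pos[lab], s=300, color="lightgray", edgecolor="black", zorder=2)
        ax.annotate(lab, pos[lab], fontsize=6, ha="center", va="center", zorder=3)
    ax.set_axis_off()
    return ax
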