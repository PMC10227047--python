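"""Transdiagnostic clustering on the five syntax measures.

Participants are clustered on standardized syntax features with a Gaussian
mixture model (full covariance, 25 restarts per k) and the number of
clusters is selected by minimizing the BIC (p * ln n - 2 * lnL; smaller is
better).  Cluster labels are re-ordered by descending cluster mean of the
relative sum of subordinate clauses, so cluster 1 is always the most
syntactically complex ("extremely complex") and the last the least
("slightly complex").

A random-forest-proximity + medoids route is provided as an alternative
partitioning method at fixed k (``rf_proximity_clusters``); BIC model
selection is defined for the mixture route only.

Whether clinical diagnosis drives cluster membership is checked per measure
with a two-way linear model: the diagnosis x cluster interaction is tested
by a partial F-test of the full model against the main-effects model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomTreesEmbedding
from sklearn.mixture import GaussianMixture

from .groupstats import TestResult, compare_measures_table

logger = logging.getLogger(__name__)

CLUSTER_NAMES = ("extremely complex", "very complex", "moderately complex", "slightly complex")


@dataclass
class ClusterResult:
    k_selected: int
    bic_by_k: Dict[int, float]
    assignments: Dict[str, int]               # participant_id -> 1-based cluster
    cluster_means: pd.DataFrame               # per-cluster means of the features
    diagnosis_composition: Optional[pd.DataFrame] = None


def _fit_gmm(X: np.ndarray, k: int, seed: int, n_init: int = 25) -> GaussianMixture:
    return GaussianMixture(
        n_components=k,
        covariance_type="full",
        n_init=n_init,
        random_state=seed,
        # variance floor on standardized features: syntactic diversity is a
        # lattice (multiples of 1/13), and without a floor a component can
        # collapse onto one lattice value and blow up the likelihood
        reg_covar=1e-4,
    ).fit(X)


def select_clusters_bic(
    features: pd.DataFrame,
    k_range: Sequence[int] = range(1, 9),
    seed: int = 0,
    n_init: int = 25,
    order_by: str = "relative_sum_sub",
    diagnosis: Optional[Mapping[str, str]] = None,
) -> ClusterResult:
    """Fit GMMs over ``k_range``, select k by BIC, return ordered assignments.

    ``features`` must be indexed by participant_id (or carry a
    ``participant_id`` column) with numeric feature columns.  Features are
    z-scored internally.  A k whose fit fails is recorded with infinite BIC.
    """
    frame = features.set_index("participant_id") if "participant_id" in features.columns else features
    frame = frame.sort_index(kind="stable")  # invariant to input row order
    ids = [str(i) for i in frame.index]
    X = frame.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("features contain missing values; impute or drop upstream")
    k_range = list(k_range)
    if not k_range or min(k_range) < 1 or max(k_range) > 10:
        raise ValueError("k_range must be within [1, 10]")
    if len(X) < 3 * max(k_range):
        raise ValueError(f"need n >= 3 * max(k) = {3 * max(k_range)}, got {len(X)}")
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd

    bic_by_k: Dict[int, float] = {}
    fits: Dict[int, GaussianMixture] = {}
    for k in k_range:
        try:
            gmm = _fit_gmm(Z, k, seed, n_init)
            bic_by_k[k] = float(gmm.bic(Z))
            fits[k] = gmm
        except (ValueError, np.linalg.LinAlgError) as exc:
            logger.warning("GMM fit failed for k=%d: %s", k, exc)
            bic_by_k[k] = float("inf")
    if not fits:
        raise RuntimeError("all mixture fits failed")
    k_selected = min(bic_by_k, key=lambda k: (bic_by_k[k], k))
    raw = fits[k_selected].predict(Z)

    # order clusters so cluster 1 has the highest mean of `order_by`
    order_col = order_by if order_by in frame.columns else frame.columns[0]
    order_vals = frame[order_col].to_numpy(dtype=float)
    means = [order_vals[raw == c].mean() if (raw == c).any() else -np.inf
             for c in range(k_selected)]
    ranking = np.argsort(means)[::-1]
    relabel = {int(old): rank + 1 for rank, old in enumerate(ranking)}
    assignments = {pid: relabel[int(c)] for pid, c in zip(ids, raw)}

    labels = np.array([assignments[pid] for pid in ids])
    cluster_means = (
        frame.assign(cluster=labels).groupby("cluster").mean().sort_index()
    )
    composition = None
    if diagnosis is not None:
        comp = pd.crosstab(labels, pd.Series([diagnosis[p] for p in ids], index=None))
        composition = comp.div(comp.sum(axis=1), axis=0)
        composition.index.name = "cluster"
    return ClusterResult(
        k_selected=int(k_selected),
        bic_by_k=bic_by_k,
        assignments=assignments,
        cluster_means=cluster_means,
        diagnosis_composition=composition,
    )


def rf_proximity_clusters(
    features: pd.DataFrame, k: int, seed: int = 0, n_estimators: int = 200
) -> Dict[str, int]:
    """Alternative partitioning: random-forest-embedding proximities + PAM medoids."""
    frame = features.set_index("participant_id") if "participant_id" in features.columns else features
    ids = [str(i) for i in frame.index]
    X = frame.to_numpy(dtype=float)
    Z = (X - X.mean(axis=0)) / np.where(X.std(axis=0) == 0, 1.0, X.std(axis=0))
    emb = RandomTreesEmbedding(n_estimators=n_estimators, random_state=seed).fit_transform(Z)
    emb = np.asarray(emb.todense())
    # proximity = share of trees placing two participants in the same leaf
    prox = emb @ emb.T / emb.shape[1] * n_estimators / emb.sum(axis=1).mean()
    dist = 1.0 - prox / prox.max()
    labels = _pam(dist, k, np.random.default_rng(seed))
    return {pid: int(c) + 1 for pid, c in zip(ids, labels)}


def _pam(dist: np.ndarray, k: int, rng: np.random.Generator, max_iter: int = 100) -> np.ndarray:
    """Plain partitioning-around-medoids on a distance matrix."""
    n = len(dist)
    medoids = rng.choice(n, size=k, replace=False)
    for _ in range(max_iter):
        labels = np.argmin(dist[:, medoids], axis=1)
        new_medoids = medoids.copy()
        for c in range(k):
            members = np.flatnonzero(labels == c)
            if len(members):
                within = dist[np.ix_(members, members)].sum(axis=1)
                new_medoids[c] = members[int(np.argmin(within))]
        if np.array_equal(np.sort(new_medoids), np.sort(medoids)):
            break
        medoids = new_medoids
    return np.argmin(dist[:, medoids], axis=1)


def interaction_effect_test(
    measure_values: Sequence[float],
    diagnosis_labels: Sequence[str],
    cluster_labels: Sequence[int],
) -> Tuple[float, float]:
    """Partial F-test of the diagnosis x cluster interaction for one measure.

    Fits ``measure ~ diagnosis + cluster`` and the model with the interaction
    added, and compares them.  Interaction terms for empty diagnosis x cluster
    cells are implicitly absent (a note is logged); a design that is rank
    deficient in its main effects is an error.
    """
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    frame = pd.DataFrame(
        {
            "y": np.asarray(measure_values, dtype=float),
            "dx": pd.Categorical([str(x) for x in diagnosis_labels]),
            "cl": pd.Categorical([str(x) for x in cluster_labels]),
        }
    )
    n_dx = frame["dx"].nunique()
    n_cl = frame["cl"].nunique()
    if n_dx < 2 or n_cl < 2:
        raise ValueError("interaction requires >= 2 diagnoses and >= 2 clusters")
    cells = frame.groupby(["dx", "cl"], observed=False).size()
    n_empty = int((cells == 0).sum())
    if n_empty:
        logger.info("%d empty diagnosis x cluster cells; their interaction terms are dropped",
                    n_empty)
    main = smf.ols("y ~ C(dx) + C(cl)", data=frame).fit()
    full = smf.ols("y ~ C(dx) * C(cl)", data=frame).fit()
    df_diff = full.df_model - main.df_model
    if df_diff <= 0:
        raise ValueError("interaction design is rank deficient (no testable interaction terms)")
    table = anova_lm(main, full)
    return float(table["F"].iloc[1]), float(table["Pr(>F)"].iloc[1])


def characterize_clusters(
    cohort: pd.DataFrame,
    assignments: Mapping[str, int],
    measures: Sequence[str],
    group_col: str = "group",
    min_size: int = 3,
) -> Tuple[pd.DataFrame, pd.DataFrame, List[TestResult]]:
    """Compare measures/covariates between clusters; report diagnosis mix.

    Clusters smaller than ``min_size`` are excluded from testing but retained
    in the composition table.  Returns (comparison table, composition table,
    raw test results).
    """
    frame = cohort.copy()
    frame["cluster"] = frame["participant_id"].map(assignments)
    if frame["cluster"].isna().any():
        missing = frame.loc[frame["cluster"].isna(), "participant_id"].tolist()
        raise ValueError(f"assignments missing for participants {missing[:5]}")
    comp = pd.crosstab(frame["cluster"], frame[group_col])
    composition = comp.div(comp.sum(axis=1), axis=0)
    sizes = frame["cluster"].value_counts()
    keep = sizes[sizes >= min_size].index
    testable = frame[frame["cluster"].isin(keep)]
    table, results = compare_measures_table(
        testable.assign(cluster=testable["cluster"].astype(int).astype(str)),
        measures,
        group_col="cluster",
    )
    return table, composition, results
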