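"""BIC-selected mixture clustering, interaction testing, characterization."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from speechsyntax.cluster import (
    characterize_clusters,
    interaction_effect_test,
    rf_proximity_clusters,
    select_clusters_bic,
)
from speechsyntax.metrics import HEADLINE_MEASURES
from speechsyntax.simulate import ClusterModeConfig, CohortConfig, cohort_frame, sample_cohort


def gaussian_frame(rng, centers, n_per, spread=1.0, d=5):
    rows = []
    for c, center in enumerate(centers):
        rows.append(rng.normal(center, spread, size=(n_per, d)))
    X = np.vstack(rows)
    frame = pd.DataFrame(X, columns=[f"f{i}" for i in range(d)])
    frame.insert(0, "participant_id", [f"p{i:03d}" for i in range(len(X))])
    truth = np.repeat(np.arange(len(centers)), n_per)
    return frame, truth


def test_single_gaussian_selects_one_cluster_in_most_seeds():
    hits = 0
    for seed in range(10):
        rng = np.random.default_rng(seed)
        frame, _ = gaussian_frame(rng, [0.0], n_per=200)
        res = select_clusters_bic(frame, k_range=range(1, 5), seed=seed)
        hits += res.k_selected == 1
    assert hits >= 9


def test_four_well_separated_gaussians_are_recovered():
    rng = np.random.default_rng(42)
    frame, truth = gaussian_frame(rng, [0, 5, 10, 15], n_per=28, spread=1.0)
    res = select_clusters_bic(frame, k_range=range(1, 8), seed=0)
    assert res.k_selected == 4
    labels = np.array([res.assignments[p] for p in frame["participant_id"]])
    assert adjusted_rand_score(truth, labels) > 0.95


def test_bic_keys_match_requested_range_and_minimum_is_selected():
    rng = np.random.default_rng(1)
    frame, _ = gaussian_frame(rng, [0, 6], n_per=40)
    res = select_clusters_bic(frame, k_range=range(1, 6), seed=0)
    assert sorted(res.bic_by_k) == [1, 2, 3, 4, 5]
    finite = {k: v for k, v in res.bic_by_k.items() if np.isfinite(v)}
    assert res.k_selected == min(finite, key=finite.get)


def test_bic_matches_brute_force_parameter_count_formula():
    from sklearn.mixture import GaussianMixture

    rng = np.random.default_rng(2)
    X = rng.normal(size=(120, 3))
    Z = (X - X.mean(0)) / X.std(0)
    gmm = GaussianMixture(2, covariance_type="full", n_init=5, random_state=0).fit(Z)
    n, d = Z.shape
    k = 2
    n_params = (k - 1) + k * d + k * d * (d + 1) // 2
    lnL = gmm.score(Z) * n
    assert gmm.bic(Z) == pytest.approx(n_params * np.log(n) - 2 * lnL)


def test_cluster_one_is_the_most_complex_by_convention():
    records = sample_cohort(CohortConfig(cluster_mode=ClusterModeConfig(), with_tokens=False),
                            seed=3)
    frame = cohort_frame(records)
    res = select_clusters_bic(frame[["participant_id"] + HEADLINE_MEASURES],
                              k_range=[4], seed=0)
    means = res.cluster_means["relative_sum_sub"]
    assert list(means.index) == sorted(means.index)
    assert means.is_monotonic_decreasing


def test_row_order_permutation_changes_nothing_but_order():
    rng = np.random.default_rng(4)
    frame, _ = gaussian_frame(rng, [0, 6, 12], n_per=30)
    res_a = select_clusters_bic(frame, k_range=range(1, 5), seed=9)
    shuffled = frame.sample(frac=1.0, random_state=1).reset_index(drop=True)
    res_b = select_clusters_bic(shuffled, k_range=range(1, 5), seed=9)
    assert res_a.k_selected == res_b.k_selected
    assert res_a.assignments == res_b.assignments


def test_planted_profiles_are_recovered_with_high_agreement():
    # four well-separated latent complexity profiles, published total n
    records = sample_cohort(
        CohortConfig(cluster_mode=ClusterModeConfig(cross_domain_coupling=0.6),
                     with_tokens=False),
        seed=7,
    )
    frame = cohort_frame(records)
    res = select_clusters_bic(frame[["participant_id"] + HEADLINE_MEASURES],
                              k_range=range(1, 8), seed=0)
    truth = frame["cluster_truth"].to_numpy()
    labels = np.array([res.assignments[p] for p in frame["participant_id"]])
    assert adjusted_rand_score(truth, labels) > 0.8


def test_rf_proximity_route_agrees_with_planted_partition_at_fixed_k():
    rng = np.random.default_rng(8)
    frame, truth = gaussian_frame(rng, [0, 8], n_per=40, d=3)
    labels = rf_proximity_clusters(frame, k=2, seed=0)
    arr = np.array([labels[p] for p in frame["participant_id"]])
    assert adjusted_rand_score(truth, arr) > 0.9


class TestInteractionEffect:
    def test_cluster_main_effect_alone_rarely_flags_an_interaction(self):
        rng = np.random.default_rng(10)
        keep = 0
        n_rep = 100
        for _ in range(n_rep):
            cl = rng.integers(1, 5, size=120)
            dx = rng.choice(["SSD", "MDD", "HC"], size=120)
            y = cl * 1.0 + rng.normal(0, 1, 120)
            _, p = interaction_effect_test(y, dx, cl)
            keep += p > 0.05
        assert keep / n_rep >= 0.90

    def test_planted_crossover_interaction_is_detected(self):
        rng = np.random.default_rng(11)
        cl = np.repeat([1, 2], 60)
        dx = np.tile(np.repeat(["SSD", "HC"], 30), 2)
        crossover = np.where((cl == 1) == (dx == "SSD"), 1.0, -1.0)
        y = 2.0 * crossover + rng.normal(0, 1, 120)
        _, p = interaction_effect_test(y, dx, cl)
        assert p < 0.01

    def test_single_cluster_design_is_degenerate(self):
        with pytest.raises(ValueError, match=">= 2"):
            interaction_effect_test([1.0, 2, 3, 4], ["a", "a", "b", "b"], [1, 1, 1, 1])


class TestCharacterization:
    @pytest.fixture(scope="class")
    @staticmethod
    def clustered_cohort():
        records = sample_cohort(
            CohortConfig(groups=(("SSD", 68), ("MDD", 76), ("HC", 80)), with_tokens=False),
            seed=13,
        )
        frame = cohort_frame(records)
        res = select_clusters_bic(frame[["participant_id"] + HEADLINE_MEASURES],
                                  k_range=[4], seed=0)
        return frame, res

    def test_composition_proportions_sum_to_one_per_cluster(self, clustered_cohort):
        frame, res = clustered_cohort
        _, composition, _ = characterize_clusters(frame, res.assignments, HEADLINE_MEASURES)
        assert np.allclose(composition.sum(axis=1), 1.0)

    def test_most_complex_cluster_is_ssd_poor(self, clustered_cohort):
        frame, res = clustered_cohort
        _, composition, _ = characterize_clusters(frame, res.assignments, HEADLINE_MEASURES)
        # SSD speech is generated least complex, so cluster 1 (most complex)
        # should contain proportionally fewer SSD participants than the last
        assert composition.loc[1, "SSD"] < composition.loc[composition.index.max(), "SSD"]
        assert composition.loc[1, "SSD"] < 1 / 3

    def test_cluster_comparison_table_covers_requested_measures(self, clustered_cohort):
        frame, res = clustered_cohort
        table, _, _ = characterize_clusters(
            frame, res.assignments, HEADLINE_MEASURES + ["semantic_vf", "neg_ftd"]
        )
        assert list(table["measure"]) == HEADLINE_MEASURES + ["semantic_vf", "neg_ftd"]
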