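"""Bipartition, forest refinement and the recursive cluster tree.

Forest sizes here (25-50 trees, few CV repetitions) are scaled down from
the library defaults so the suite stays fast; the contracts under test do
not depend on ensemble size.
"""

import numpy as np
import pandas as pd
import pytest

from orgsc import synthetic
from orgsc.cluster import (RecursiveRandomForestClusterer, pearson_bipartition,
                           refine_bipartition)


def correlated_blocks(rng, n_a=12, n_b=12, n_feat=30):
    """Two sample blocks: high within-block, negative between-block correlation."""
    base_a = rng.normal(size=n_feat)
    base_b = -base_a + rng.normal(0, 0.3, n_feat)
    rows = [base_a + rng.normal(0, 0.35, n_feat) for _ in range(n_a)]
    rows += [base_b + rng.normal(0, 0.35, n_feat) for _ in range(n_b)]
    return np.array(rows), np.array([0] * n_a + [1] * n_b)


def planted_binary(rng, n_per=60, n_feat=30, noise_frac=0.0):
    """Separable two-class binary matrix, optionally with boundary samples."""
    profile_a = np.r_[np.full(n_feat // 2, 0.9), np.full(n_feat - n_feat // 2, 0.1)]
    profile_b = 1 - profile_a
    X = np.vstack([rng.random((n_per, n_feat)) < profile_a,
                   rng.random((n_per, n_feat)) < profile_b]).astype(float)
    y = np.array([0] * n_per + [1] * n_per)
    n_noise = int(round(noise_frac * 2 * n_per))
    if n_noise:
        Xn = (rng.random((n_noise, n_feat)) < 0.5).astype(float)
        X = np.vstack([X, Xn])
        y = np.r_[y, np.full(n_noise, -9)]
    return X, y


class TestBipartition:
    def test_correlation_blocks_recovered_exactly(self, rng):
        X, truth = correlated_blocks(rng)
        labels = pearson_bipartition(X)
        assert (labels == truth).all() or (labels == 1 - truth).all()

    def test_duplicated_rows_colocate(self, rng):
        X, _ = correlated_blocks(rng)
        X = np.vstack([X, X[0], X[0]])
        labels = pearson_bipartition(X)
        assert labels[0] == labels[-1] == labels[-2]

    def test_affine_rescaling_of_a_row_is_invisible(self, rng):
        X, _ = correlated_blocks(rng)
        labels = pearson_bipartition(X)
        X2 = X.copy()
        X2[3] = 2 * X2[3] + 5  # Pearson distance is affine-invariant
        assert (pearson_bipartition(X2) == labels).all()

    def test_zero_variance_sample_attached_to_nearest_neighbor(self, rng):
        X, _ = correlated_blocks(rng)
        flat = np.full((1, X.shape[1]), X[0].mean())
        labels = pearson_bipartition(np.vstack([X, flat]))
        assert labels[-1] in (0, 1)


class TestRefineBipartition:
    def test_separable_matrix_keeps_planted_labels(self, rng):
        X, y = planted_binary(rng, n_per=40)
        res = refine_bipartition(X, y, cv_runs=5, n_estimators=25, seed=0)
        assert res.ok
        assert res.unassigned.sum() == 0
        agree = (res.labels == y).mean()
        assert agree in (0.0, 1.0) or agree == 1.0

    def test_boundary_samples_enriched_in_unassigned(self):
        """The vote-probability gate prunes boundary samples, not clean ones.

        Boundary samples are per-feature mixtures of the two class
        profiles, so their held-out votes concentrate near 0.5.  A
        forest's expected vote for such a sample still varies by ~0.07
        across samples (each sample's realized features are reused by
        every tree), so the 0.55 gate removes a large fraction of them —
        not all — while leaving well-classified samples untouched.
        """
        dropped = total = clean_dropped = clean_total = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n_per, n_feat = 60, 40
            half = n_feat // 2
            mu_a = np.r_[np.full(half, 1.0), np.full(n_feat - half, -1.0)]
            A = mu_a + rng.normal(0, 0.5, (n_per, n_feat))
            B = -mu_a + rng.normal(0, 0.5, (n_per, n_feat))
            n_noise = 6
            Xn = np.empty((n_noise, n_feat))
            for i in range(n_noise):
                pick_a = rng.permutation(n_feat) < half
                Xn[i] = np.where(pick_a, mu_a, -mu_a) + rng.normal(0, 0.5, n_feat)
            X = np.vstack([A, B, Xn])
            noise = np.r_[np.zeros(2 * n_per, bool), np.ones(n_noise, bool)]
            init = pearson_bipartition(X)
            res = refine_bipartition(X, init, cv_runs=10, n_estimators=50,
                                     seed=seed)
            assert res.ok
            dropped += int(res.unassigned[noise].sum())
            total += n_noise
            clean_dropped += int(res.unassigned[~noise].sum())
            clean_total += 2 * n_per
        assert dropped / total >= 0.25
        assert clean_dropped / clean_total <= 0.02
        assert dropped / total > 10 * max(clean_dropped / clean_total, 1e-9)

    def test_deterministic_for_fixed_seed(self, rng):
        X, y = planted_binary(rng, n_per=30)
        a = refine_bipartition(X, y, cv_runs=3, n_estimators=25, seed=5)
        b = refine_bipartition(X, y, cv_runs=3, n_estimators=25, seed=5)
        assert (a.labels == b.labels).all()
        assert (a.unassigned == b.unassigned).all()
        np.testing.assert_allclose(a.vote_probabilities, b.vote_probabilities)

    def test_raising_keep_gate_never_shrinks_unassigned(self, rng):
        X, y = planted_binary(rng, n_per=40, noise_frac=0.1)
        init = pearson_bipartition(X)
        low = refine_bipartition(X, init, keep_gate=0.55, cv_runs=5,
                                 n_estimators=25, seed=3)
        high = refine_bipartition(X, init, keep_gate=0.75, cv_runs=5,
                                  n_estimators=25, seed=3)
        if low.ok and high.ok:
            assert set(np.flatnonzero(low.unassigned)) <= set(
                np.flatnonzero(high.unassigned))


class TestRecursiveClusterer:
    def test_tree_partitions_samples_exactly_once(self, rng):
        mat, _ = synthetic.simulate_binary_regulon_matrix(
            n_cells_per_group=40, n_groups=2, seed=0)
        est = RecursiveRandomForestClusterer(cv_runs=5, n_estimators=25,
                                             random_state=0).fit(mat)
        assigned = np.flatnonzero(est.labels_ >= 0)
        unassigned = [i for i, _ in est.unassigned_]
        assert sorted(assigned.tolist() + unassigned) == list(range(mat.shape[0]))

    def test_identical_tree_across_runs_at_fixed_seed(self, rng):
        mat, _ = synthetic.simulate_binary_regulon_matrix(
            n_cells_per_group=40, n_groups=2, seed=1)
        a = RecursiveRandomForestClusterer(cv_runs=5, n_estimators=25,
                                           random_state=9).fit(mat)
        b = RecursiveRandomForestClusterer(cv_runs=5, n_estimators=25,
                                           random_state=9).fit(mat)
        assert (a.labels_ == b.labels_).all()
        assert a.tree_["n_samples"] == b.tree_["n_samples"]

    def test_nested_hierarchy_recovered_in_order(self):
        """2 super-groups, one splitting in two: topology matches the truth."""
        rng = np.random.default_rng(4)
        n = 50
        cols = {}
        labels = np.array(["A1"] * n + ["A2"] * n + ["B"] * (2 * n))
        is_a = np.r_[np.ones(2 * n, bool), np.zeros(2 * n, bool)]
        is_a1 = np.r_[np.ones(n, bool), np.zeros(3 * n, bool)]
        is_a2 = np.r_[np.zeros(n, bool), np.ones(n, bool), np.zeros(2 * n, bool)]
        for i in range(10):  # super-group A vs B signature
            cols[f"super{i}"] = rng.random(4 * n) < np.where(is_a, 0.9, 0.1)
        for i in range(10):  # sub-signatures inside A, strong enough that a
            # cell's realized profile almost never favors the sibling subgroup
            cols[f"a1_{i}"] = rng.random(4 * n) < np.where(is_a1, 0.95, 0.05)
            cols[f"a2_{i}"] = rng.random(4 * n) < np.where(is_a2, 0.95, 0.05)
        for i in range(6):
            cols[f"noise{i}"] = rng.random(4 * n) < 0.3
        mat = pd.DataFrame({k: v.astype(int) for k, v in cols.items()})
        est = RecursiveRandomForestClusterer(cv_runs=5, n_estimators=50,
                                             random_state=2).fit(mat)
        assert est.n_leaves_ == 3
        # every leaf must be (near-)pure w.r.t. the planted hierarchy
        for leaf in range(est.n_leaves_):
            members = labels[est.labels_ == leaf]
            top = pd.Series(members).value_counts(normalize=True).iloc[0]
            assert top >= 0.95
        # B stays one leaf; A is the side that split
        leaf_of_b = pd.Series(est.labels_[labels == "B"]).mode()[0]
        assert (est.labels_[labels == "B"] == leaf_of_b).mean() >= 0.95

    def test_too_few_samples_is_an_error(self, rng):
        X = rng.random((12, 5))
        with pytest.raises(ValueError, match="at least"):
            RecursiveRandomForestClusterer(min_leaf=10).fit(X)
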