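"""Unit and property tests for the per-pair conditional covariance statistics."""

import numpy as np
import pytest
from scipy import stats as sps

from acarp.data import ItemResponseMatrix
from acarp.pairstats import (
    all_pair_stats,
    conditioning_groups,
    fit_pair_predictor,
    group_covariance,
    mcc_statistic,
    mh_variance,
    pair_count,
    pair_indices,
    split_sample,
    z_statistic,
)
from acarp.simulate import SimulationDesign, simulate_design


class TestPairCombinatorics:
    @pytest.mark.parametrize("J,expected", [(10, 45), (2, 1), (30, 435), (3, 3)])
    def test_pair_count(self, J, expected):
        assert pair_count(J) == expected

    def test_pair_count_rejects_singleton(self):
        with pytest.raises(ValueError):
            pair_count(1)

    def test_canonical_order_is_lexicographic(self):
        pairs = pair_indices(4)
        assert pairs.tolist() == [[0, 1], [0, 2], [0, 3], [1, 2], [1, 3], [2, 3]]


class TestSplitSample:
    def test_sizes_round_fraction(self, bernoulli_matrix):
        X = ItemResponseMatrix(np.zeros((10, 3), dtype=int))
        sp = split_sample(X, 0.3, seed=1)
        assert len(sp.train_rows) == 3 and len(sp.test_rows) == 7

    def test_thirty_percent_of_thousand(self):
        X = ItemResponseMatrix(np.zeros((1000, 3), dtype=int))
        sp = split_sample(X, 0.3, seed=9)
        assert len(sp.train_rows) == 300

    def test_partition_and_determinism(self, bernoulli_matrix):
        a = split_sample(bernoulli_matrix, 0.3, seed=4)
        b = split_sample(bernoulli_matrix, 0.3, seed=4)
        assert np.array_equal(a.train_rows, b.train_rows)
        merged = np.sort(np.concatenate([a.train_rows, a.test_rows]))
        assert np.array_equal(merged, np.arange(bernoulli_matrix.n_subjects))
        assert not np.intersect1d(a.train_rows, a.test_rows).size

    @pytest.mark.parametrize("fraction", [0.0, 1.0, -0.2, 1.5])
    def test_invalid_fraction(self, bernoulli_matrix, fraction):
        with pytest.raises(ValueError):
            split_sample(bernoulli_matrix, fraction)

    def test_degenerate_split(self):
        X = ItemResponseMatrix(np.zeros((3, 3), dtype=int))
        with pytest.raises(ValueError, match="degenerate"):
            split_sample(X, 0.01)


class TestPairPredictor:
    def test_constant_target(self):
        # X_i + X_j constant at 1: intercept 1, zero weights
        vals = np.array([[1, 0, 0, 1], [0, 1, 1, 0], [1, 0, 1, 1], [0, 1, 0, 0]])
        pred = fit_pair_predictor(ItemResponseMatrix(vals), (0, 1))
        assert pred.intercept == pytest.approx(1.0, abs=1e-10)
        assert np.allclose(pred.weights, 0.0, atol=1e-10)

    def test_perfect_linear_fit_three_items(self):
        # single remaining item equals X_i + X_j - 1 exactly
        xi = np.array([1, 0, 1, 0, 1, 1])
        xj = np.array([1, 1, 0, 1, 1, 0])
        rest = xi + xj - 1
        assert set(rest) <= {0, 1}
        pred = fit_pair_predictor(ItemResponseMatrix(np.column_stack([xi, xj, rest])), (0, 1))
        assert pred.intercept == pytest.approx(1.0, abs=1e-9)
        assert pred.weights[0] == pytest.approx(1.0, abs=1e-9)

    def test_matches_normal_equations_oracle(self, rng):
        vals = (rng.random((6, 5)) < 0.5).astype(int)
        X = ItemResponseMatrix(vals)
        pred = fit_pair_predictor(X, (1, 3))
        rest = vals[:, [0, 2, 4]].astype(float)
        A = np.column_stack([np.ones(6), rest])
        beta, *_ = np.linalg.lstsq(A, vals[:, 1] + vals[:, 3], rcond=None)
        assert pred.intercept == pytest.approx(beta[0], abs=1e-8)
        assert np.allclose(pred.weights, beta[1:], atol=1e-8)

    def test_insufficient_rows(self):
        X = ItemResponseMatrix(np.zeros((1, 4), dtype=int))
        with pytest.raises(ValueError, match="insufficient"):
            fit_pair_predictor(X, (0, 1))


class TestConditioningGroups:
    def test_twenty_distinct_scores_give_ten_pairs(self):
        from acarp.pairstats import PairPredictor, _pair_index

        pred = PairPredictor(_pair_index(0, 1, 3), intercept=0.0, weights=np.array([1.0]))
        # third-item scores 0..19 cannot be binary; emulate via direct scoring
        scores = np.arange(20.0)
        from acarp.pairstats import _labels_from_edges, _quantile_edges

        labels = _labels_from_edges(scores, _quantile_edges(scores, 10))
        sizes = np.bincount(labels)
        assert len(sizes) == 10 and (sizes == 2).all()

    def test_total_tie_collapses_to_one_group(self):
        X = ItemResponseMatrix(np.tile([1, 0, 1], (8, 1)))
        pred = fit_pair_predictor(X, (0, 1))
        groups = conditioning_groups(X, pred, C=10)
        assert groups.n_groups == 1 and groups.degenerate
        assert groups.group_sizes[0] == 8

    def test_labels_are_function_of_score(self, rng):
        vals = (rng.random((200, 6)) < 0.5).astype(int)
        X = ItemResponseMatrix(vals)
        pred = fit_pair_predictor(X, (0, 1))
        groups = conditioning_groups(X, pred, C=10)
        scores = pred.scores(X)
        for s in np.unique(scores):
            assert len(np.unique(groups.labels[scores == s])) == 1
        assert groups.n_groups <= 10
        assert groups.group_sizes.sum() == 200

    def test_rejects_single_group_target(self, bernoulli_matrix):
        pred = fit_pair_predictor(bernoulli_matrix, (0, 1))
        with pytest.raises(ValueError):
            conditioning_groups(bernoulli_matrix, pred, C=1)


class TestGroupStatistics:
    def test_group_covariance_cases(self):
        assert group_covariance([1, 1, 1], [0, 1, 0]) == pytest.approx(0.0)
        assert group_covariance([1, 0], [1, 0]) == pytest.approx(0.25)
        assert group_covariance([1, 0], [0, 1]) == pytest.approx(-0.25)
        with pytest.raises(ValueError):
            group_covariance([], [])

    def _groups(self, labels):
        from acarp.pairstats import ConditioningGroups, _pair_index

        labels = np.asarray(labels)
        return ConditioningGroups(
            pair=_pair_index(0, 1, 3),
            labels=labels,
            group_sizes=np.bincount(labels),
            target_groups=10,
            cut_points=np.array([]),
        )

    def test_mcc_is_weighted_mean_of_group_covariances(self, rng):
        labels = rng.integers(0, 4, size=50)
        xi = (rng.random(50) < 0.5).astype(float)
        xj = (rng.random(50) < 0.5).astype(float)
        groups = self._groups(labels)
        T, mcc = mcc_statistic(groups, xi, xj)
        expected = sum(
            (labels == c).sum() * group_covariance(xi[labels == c], xj[labels == c])
            for c in np.unique(labels)
        )
        assert T == pytest.approx(expected, abs=1e-12)
        assert mcc == pytest.approx(expected / 50, abs=1e-12)

    def test_single_group_reduces_to_sample_covariance(self, rng):
        xi = (rng.random(30) < 0.5).astype(float)
        xj = (rng.random(30) < 0.5).astype(float)
        _, mcc = mcc_statistic(self._groups(np.zeros(30, dtype=int)), xi, xj)
        assert mcc == pytest.approx(group_covariance(xi, xj), abs=1e-12)

    def test_mh_variance_balanced_group(self):
        # 4 subjects, 2 ones on each item: 2*2*2*2 / (16*3) = 1/3
        groups = self._groups([0, 0, 0, 0])
        v = mh_variance(groups, [1, 1, 0, 0], [1, 0, 1, 0])
        assert v == pytest.approx(1.0 / 3.0)

    def test_mh_variance_constant_item_contributes_zero(self):
        groups = self._groups([0, 0, 0])
        assert mh_variance(groups, [1, 1, 1], [1, 0, 1]) == 0.0

    def test_mh_variance_additive_over_groups(self):
        one = mh_variance(self._groups([0, 0, 0, 0]), [1, 1, 0, 0], [1, 0, 1, 0])
        two = mh_variance(
            self._groups([0, 0, 0, 0, 1, 1, 1, 1]),
            [1, 1, 0, 0, 1, 1, 0, 0],
            [1, 0, 1, 0, 1, 0, 1, 0],
        )
        assert two == pytest.approx(2 * one)

    def test_matches_hypergeometric_variance(self):
        # enumerate all 2x2 tables with margins (2, 2) of n=4: the count in
        # cell (1,1) is hypergeometric; MH variance must match its variance
        var = sps.hypergeom(4, 2, 2).var()
        assert mh_variance(self._groups([0] * 4), [1, 1, 0, 0], [1, 0, 1, 0]) == pytest.approx(var)


class TestZStatistic:
    def test_continuity_arithmetic(self):
        z_on, _ = z_statistic(-2.0, 4.0, continuity=True)
        z_off, _ = z_statistic(-2.0, 4.0, continuity=False)
        assert z_on == pytest.approx(-0.75)
        assert z_off == pytest.approx(-1.0)

    def test_zero_z_gives_half(self):
        z, p = z_statistic(0.0, 4.0, continuity=False)
        assert p == pytest.approx(0.5)

    def test_continuity_is_conservative(self, rng):
        for _ in range(20):
            T, V = rng.normal(scale=3), rng.uniform(0.5, 5)
            z_on, p_on = z_statistic(T, V, True)
            z_off, p_off = z_statistic(T, V, False)
            assert z_on > z_off and p_on >= p_off

    def test_zero_variance_flagged_undefined(self):
        z, p = z_statistic(-1.0, 0.0)
        assert np.isnan(z) and np.isnan(p)
        with pytest.raises(ValueError):
            z_statistic(1.0, -1.0)


class TestAllPairStats:
    def test_vector_lengths_for_ten_items(self):
        X = simulate_design(SimulationDesign(J=10, N=300, scenario="dim0", seed=2))
        train, test = all_pair_stats(X, split_sample(X, 0.3, 3))
        assert train.K == test.K == 45

    def test_mcc_bounds_and_nonnegative_variance(self, dim0_matrix):
        train, test = all_pair_stats(dim0_matrix, split_sample(dim0_matrix, 0.3, 1))
        for vec in (train, test):
            assert (np.abs(vec.mcc) <= 0.25 + 1e-12).all()
            assert (vec.variance >= 0).all()

    def test_row_permutation_invariance(self, rng):
        vals = (rng.random((80, 5)) < 0.5).astype(int)
        X = ItemResponseMatrix(vals)
        sp = split_sample(X, 0.3, 7)
        tr1, te1 = all_pair_stats(X, sp)
        # permute subjects and remap the split membership accordingly
        perm = rng.permutation(80)
        X2 = ItemResponseMatrix(vals[perm])
        inv = np.argsort(perm)
        from acarp.pairstats import SampleSplit

        sp2 = SampleSplit(
            np.sort(inv[sp.train_rows]), np.sort(inv[sp.test_rows]), sp.fraction, sp.seed
        )
        tr2, te2 = all_pair_stats(X2, sp2)
        assert np.allclose(te1.numerator, te2.numerator, atol=1e-10)
        assert np.allclose(tr1.mcc, tr2.mcc, atol=1e-10)

    def test_item_recoding_flips_pair_numerator_restscore(self, rng):
        # recoding item i -> 1 - i leaves the pairwise rest score of (i, j)
        # unchanged, so that pair's conditioning groups are identical and its
        # numerator flips sign exactly (continuity off)
        vals = (rng.random((120, 5)) < 0.5).astype(int)
        X = ItemResponseMatrix(vals)
        sp = split_sample(X, 0.3, 5)
        _, te = all_pair_stats(X, sp, continuity=False, conditioning="restscore")
        flipped = vals.copy()
        flipped[:, 0] = 1 - flipped[:, 0]
        _, te2 = all_pair_stats(ItemResponseMatrix(flipped), sp, continuity=False, conditioning="restscore")
        k01 = 0  # pair (0, 1) is first in canonical order
        assert te2.numerator[k01] == pytest.approx(-te.numerator[k01], abs=1e-10)

    def test_naive_loop_oracle(self, rng):
        # MCC and MH variance recomputed subject-by-subject must match the
        # vectorized implementation to numerical precision
        from acarp.pairstats import fit_carp_model, _labels_from_edges

        vals = (rng.random((50, 5)) < 0.5).astype(int)
        X = ItemResponseMatrix(vals)
        sp = split_sample(X, 0.3, 11)
        model = fit_carp_model(X, sp)
        _, te = all_pair_stats(X, sp)
        test_vals = vals[sp.test_rows]
        scores = model.scores(test_vals)
        for k, (i, j) in enumerate(model.pairs):
            lab = _labels_from_edges(scores[:, k], model.test_cut_points[k])
            T = V = 0.0
            for c in np.unique(lab):
                xi = test_vals[lab == c, i].astype(float)
                xj = test_vals[lab == c, j].astype(float)
                n_c = len(xi)
                T += n_c * (np.mean(xi * xj) - xi.mean() * xj.mean())
                if n_c >= 2:
                    mi, mj = xi.sum(), xj.sum()
                    V += mi * (n_c - mi) * mj * (n_c - mj) / (n_c**2 * (n_c - 1))
            assert te.numerator[k] == pytest.approx(T, abs=1e-12)
            assert te.variance[k] == pytest.approx(V, abs=1e-12)

    def test_degenerate_pairs_flagged(self):
        vals = np.zeros((40, 4), dtype=int)
        vals[:, 3] = np.arange(40) % 2  # three constant items
        X = ItemResponseMatrix(vals)
        _, te = all_pair_stats(X, split_sample(X, 0.3, 1))
        assert te.degenerate.all()
        assert np.isnan(te.z).all()

    def test_null_pvalues_uniform(self):
        # zero-dimensional model, continuity off: pair p-values across
        # replications are approximately uniform (KS at the 1% level)
        ps = []
        for r in range(250):
            X = simulate_design(SimulationDesign(J=5, N=1000, scenario="dim0", seed=3000 + r))
            _, te = all_pair_stats(X, split_sample(X, 0.3, 6000 + r), continuity=False)
            ps.append(te.p[~np.isnan(te.p)])
        ps = np.concatenate(ps)
        assert ps.size >= 2000
        assert sps.kstest(ps, "uniform").pvalue > 0.01
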