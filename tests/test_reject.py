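"""Chow threshold, per-sigma classifiers, sparse ensemble and regression."""

import itertools
from dataclasses import dataclass

import numpy as np
import pytest

from trackreject.datasets import ThresholdPair, threshold_pairs
from trackreject import reject as rj


class TestSmote:
    def test_balances_classes(self, rng):
        X = rng.normal(size=(60, 4))
        y = np.array([1] * 10 + [0] * 50)
        Xb, yb = rj.smote_resample(X, y, rng=rng)
        assert (yb == 1).sum() == (yb == 0).sum() == 50

    def test_noop_on_balanced_input(self, rng):
        X = rng.normal(size=(20, 3))
        y = np.array([0, 1] * 10)
        Xb, yb = rj.smote_resample(X, y, rng=rng)
        assert Xb.shape == X.shape
        assert np.array_equal(yb, y)

    def test_synthetic_points_interpolate_minority(self, rng):
        # minority samples on a line segment: synthetic points stay on it
        X = np.zeros((40, 2))
        X[:8, 0] = np.linspace(0.0, 1.0, 8)  # minority along x axis
        X[8:, 1] = np.linspace(5.0, 6.0, 32)
        y = np.array([1] * 8 + [0] * 32)
        Xb, yb = rj.smote_resample(X, y, rng=rng)
        synth = Xb[40:]
        assert np.allclose(synth[:, 1], 0.0)
        assert np.all((synth[:, 0] >= 0.0) & (synth[:, 0] <= 1.0))


class TestChowThreshold:
    def test_candidate_grid_endpoints(self):
        assert rj.TAU_GRID[0] == -200.0
        assert rj.TAU_GRID[-1] == 200.0
        assert len(rj.TAU_GRID) == 401

    def test_separable_scores_perfect_split(self):
        ll = np.array([-150.0] * 10 + [100.0] * 30)  # lost windows score low
        y = np.array([1] * 10 + [0] * 30)
        model = rj.fit_chow_threshold(ll, y)
        pred = model.predict(ll)
        assert np.array_equal(pred, y)

    def test_random_labels_no_crash(self, rng):
        ll = rng.uniform(-180, 180, 200)
        y = rng.integers(0, 2, 200)
        model = rj.fit_chow_threshold(ll, y)
        assert -200.0 <= model.tau <= 200.0

    def test_tie_break_smallest_tau(self):
        # all-reject is optimal everywhere above the max score; the smallest
        # tau achieving the best F1 must be returned
        ll = np.array([-10.0, -10.0, 5.0])
        y = np.array([1, 1, 1])
        with pytest.raises(ValueError):
            rj.fit_chow_threshold(ll, y)  # single class
        y = np.array([1, 1, 0])
        model = rj.fit_chow_threshold(ll, y)
        assert model.tau == -9.0  # first grid point above -10

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            rj.fit_chow_threshold(np.array([1.0, 2.0]), np.array([0, 0]))


class TestSigmaClassifier:
    def test_linear_separable_zero_training_error(self, rng):
        X = np.vstack([rng.normal(-3, 0.3, (30, 2)), rng.normal(3, 0.3, (30, 2))])
        y = np.array([0] * 30 + [1] * 30)
        model = rj.fit_sigma_classifier(X, y, kind="linear", smote=False, seed=0)
        assert np.array_equal(model.predict(X), y)

    def test_forest_score_is_tree_vote_fraction(self, rng):
        X = rng.normal(size=(80, 3))
        y = (X[:, 0] > 0).astype(int)
        model = rj.fit_sigma_classifier(X, y, kind="forest", smote=False, seed=0)
        x0 = X[:5]
        votes = np.stack([t.predict(x0) for t in model.estimator.estimators_])
        assert np.allclose(model.score(x0), votes.mean(axis=0))
        assert np.all((model.score(X) >= 0) & (model.score(X) <= 1))

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            rj.fit_sigma_classifier(rng.normal(size=(10, 2)), np.zeros(10), seed=0)

    def test_unknown_kind_rejected(self, rng):
        X = rng.normal(size=(10, 2))
        y = np.array([0, 1] * 5)
        with pytest.raises(ValueError):
            rj.fit_sigma_classifier(X, y, kind="boosted", seed=0)


def _brute_force_best_ops(scores, y, goal_p, goal_r):
    """Exhaustive sweep over all cutpoints (the oracle for classifier_range)."""
    best = None
    for phi in list(np.unique(scores)) + [np.inf]:
        pred = (scores >= phi).astype(int)
        tp = ((pred == 1) & (y == 1)).sum()
        fp = ((pred == 1) & (y == 0)).sum()
        fn = ((pred == 0) & (y == 1)).sum()
        if tp + fp == 0 or tp + fn == 0:
            continue
        p, r = tp / (tp + fp), tp / (tp + fn)
        if p >= goal_p and r >= goal_r and (best is None or p + r > best[1] + best[2]):
            best = (phi, p, r)
    return best


class TestClassifierRange:
    @pytest.fixture()
    def toy(self, rng):
        X = rng.normal(size=(120, 3))
        score_var = X @ np.array([1.0, 0.5, -0.2])
        sigmas = threshold_pairs()[:4]
        labels = np.stack([(score_var + rng.normal(0, 0.5 + 0.4 * i, 120) > 0).astype(int)
                           for i in range(4)], axis=1)
        model = rj.fit_sigma_classifier(X, labels[:, 0], kind="linear", smote=False, seed=0)
        return X, labels, sigmas, model

    def test_self_coverage_with_achievable_goals(self, toy):
        X, labels, sigmas, model = toy
        out = rj.classifier_range(model, X, labels, sigmas, goal_p=0.6, goal_r=0.6)
        assert sigmas[0].index in out

    def test_perfect_goals_on_noisy_scores_empty(self, toy):
        X, labels, sigmas, model = toy
        noisy_col = 3  # noisiest labels cannot be perfectly separated
        out = rj.classifier_range(model, X, labels, sigmas, goal_p=1.0, goal_r=1.0)
        assert noisy_col + 1 not in out or out == {}

    def test_matches_brute_force_cutpoint_sweep(self, toy):
        X, labels, sigmas, model = toy
        goal_p, goal_r = 0.7, 0.7
        out = rj.classifier_range(model, X, labels, sigmas, goal_p, goal_r)
        scores = model.score(X)
        for col, s in enumerate(sigmas):
            brute = _brute_force_best_ops(scores, labels[:, col], goal_p, goal_r)
            if brute is None:
                assert s.index not in out
            else:
                assert s.index in out
                phi, p, r = out[s.index]
                assert p + r == pytest.approx(brute[1] + brute[2], abs=1e-12)

    def test_invalid_goals_rejected(self, toy):
        X, labels, sigmas, model = toy
        with pytest.raises(ValueError):
            rj.classifier_range(model, X, labels, sigmas, goal_p=0.0, goal_r=0.5)


@dataclass
class _StubModel:
    sigma_index: int


def _brute_min_cover(range_sets, universe):
    for size in range(1, len(range_sets) + 1):
        for combo in itertools.combinations(range(len(range_sets)), size):
            if set().union(*(range_sets[i] for i in combo)) >= universe:
                return size
    return None


class TestSparseEnsemble:
    def _ranges_to_dicts(self, range_sets):
        return [{s: (0.5, 0.9, 0.9) for s in rs} for rs in range_sets]

    def test_single_covering_candidate(self):
        sigmas = threshold_pairs()
        all_cover = [set(s.index for s in sigmas)]
        ens = rj.build_sparse_ensemble([_StubModel(1)], None, None, sigmas, 0.9, 0.9,
                                       ranges=self._ranges_to_dicts(all_cover))
        assert ens.size == 1

    def test_matches_brute_force_set_cover(self, rng):
        sigmas = threshold_pairs()
        universe = set(s.index for s in sigmas)
        for trial in range(50):
            r = np.random.default_rng(trial)
            n_cand = int(r.integers(2, 9))
            range_sets = []
            for _ in range(n_cand):
                lo = int(r.integers(1, 21))
                hi = int(r.integers(lo, 21))
                range_sets.append(set(range(lo, hi + 1)))
            if not set().union(*range_sets) >= universe:
                range_sets[0] = universe.copy() if r.random() < 0.3 else range_sets[0]
            covered = set().union(*range_sets)
            cands = [_StubModel(i) for i in range(n_cand)]
            dicts = self._ranges_to_dicts(range_sets)
            if covered >= universe:
                ens = rj.build_sparse_ensemble(cands, None, None, sigmas, 0.9, 0.9, ranges=dicts)
                assert ens.size == _brute_min_cover(range_sets, universe)
            else:
                with pytest.raises(rj.UncoverableError) as ei:
                    rj.build_sparse_ensemble(cands, None, None, sigmas, 0.9, 0.9, ranges=dicts)
                assert set(ei.value.orphans) == universe - covered

    def test_assignment_prefers_highest_combined_score(self):
        sigmas = threshold_pairs()[:3]
        ranges = [{1: (0.1, 0.8, 0.8), 2: (0.1, 0.9, 0.9), 3: (0.1, 0.9, 0.9)},
                  {1: (0.2, 0.95, 0.9), 2: (0.2, 0.7, 0.7)}]
        # both candidates are needed? no: candidate 0 covers all three alone
        ens = rj.build_sparse_ensemble([_StubModel(1), _StubModel(2)], None, None,
                                       sigmas, 0.9, 0.9, ranges=ranges)
        assert ens.size == 1
        assert ens.assignment[1][0] == 0

    def test_greedy_fallback_on_large_pools(self):
        sigmas = threshold_pairs()
        universe = [s.index for s in sigmas]
        # 25 candidates, each covering two adjacent sigmas plus one full cover
        range_sets = [set(universe[i % 19:i % 19 + 2]) for i in range(24)] + [set(universe)]
        dicts = self._ranges_to_dicts(range_sets)
        cands = [_StubModel(i) for i in range(25)]
        ens = rj.build_sparse_ensemble(cands, None, None, sigmas, 0.9, 0.9, ranges=dicts)
        assert ens.size <= 10  # greedy picks the full cover immediately here


class TestRegression:
    def test_linear_targets_recovered(self, rng):
        X = rng.normal(size=(100, 5))
        w1, w2 = rng.normal(size=5), rng.normal(size=5)
        t = np.stack([np.abs(X @ w1), np.abs(X @ w2)], axis=1)
        model = rj.fit_regressor(X, t, kind="forest", seed=0)
        pred = model.predict(X)
        assert pred.shape == (100, 2)
        assert np.all(pred >= 0)

    def test_constant_targets_predicted(self, rng):
        X = rng.normal(size=(50, 3))
        t = np.full((50, 2), 0.07)
        model = rj.fit_regressor(X, t, kind="linear", seed=0)
        assert np.allclose(model.predict(X), 0.07, atol=1e-8)

    def test_forest_beats_linear_on_step_target(self, rng):
        X = rng.uniform(-1, 1, (200, 1))
        t = np.stack([(X[:, 0] > 0) * 0.2, (X[:, 0] > 0) * 0.2], axis=1)
        lin = rj.fit_regressor(X, t, kind="linear", seed=0)
        rf = rj.fit_regressor(X, t, kind="forest", seed=0)
        rmse = lambda m: np.sqrt(np.mean((m.predict(X) - t) ** 2))
        assert rmse(rf) < rmse(lin)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            rj.fit_regressor(np.zeros((1, 2)), np.zeros((1, 2)), kind="linear")


class TestRegressionDecision:
    SIGMA1 = ThresholdPair(d=0.05, a=0.13, index=1)

    @pytest.mark.parametrize("pred,expected", [
        ((0.04, 0.10), 0),   # inside both tolerances
        ((0.06, 0.10), 1),   # distance exceeds
        ((0.04, 0.20), 1),   # angle exceeds
        ((0.05, 0.13), 0),   # boundary kept
        ((-0.02, -0.1), 0),  # negative predictions clamped to zero
    ])
    def test_rule(self, pred, expected):
        assert rj.regression_decision(np.array(pred), self.SIGMA1)[0] == expected

    def test_monotone_in_sigma(self, rng):
        sigmas = threshold_pairs()
        preds = rng.uniform(0, 0.3, (50, 2))
        decisions = np.stack([rj.regression_decision(preds, s) for s in sigmas], axis=1)
        # rejected under a tolerant sigma implies rejected under stricter ones
        assert np.all(np.diff(decisions, axis=1) <= 0)
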