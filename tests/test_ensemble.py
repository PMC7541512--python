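"""Base learners, evaluation metrics, gating and the weighted ensemble."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rangecast import (
    EnsembleConfig,
    Layer,
    auroc,
    binarize,
    build_ensemble,
    fit_base,
    optimize_cutpoint,
    predict_ensemble,
    split_data,
    tss,
    variable_contribution,
)
from rangecast.ensemble import (
    BaseFit,
    EvalResult,
    NoAdmissibleModelsError,
    UndefinedMetricError,
    evaluate_fit,
)

from conftest import make_stack


def _toy_separable(n=40, seed=0):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame({"a": np.r_[rng.normal(-3, 0.5, n), rng.normal(3, 0.5, n)],
                      "b": rng.normal(size=2 * n)})
    y = np.r_[np.zeros(n, int), np.ones(n, int)]
    return X, y


class TestSplitData:
    def test_stratification_arithmetic_10_10(self):
        X = pd.DataFrame({"a": np.arange(20.0)})
        y = np.r_[np.ones(10, int), np.zeros(10, int)]
        train, hX, hy = split_data(X, y, 0.8, folds=2, seed=0)
        assert (hy == 1).sum() == 2 and (hy == 0).sum() == 2
        for fold in (1, 2):
            in_fold = train.folds == fold
            assert abs((train.labels[in_fold] == 1).sum() - 4) <= 1

    def test_same_seed_identical_assignment(self):
        X = pd.DataFrame({"a": np.arange(30.0)})
        y = (np.arange(30) % 2).astype(int)
        t1, h1, _ = split_data(X, y, 0.8, 5, seed=9)
        t2, h2, _ = split_data(X, y, 0.8, 5, seed=9)
        np.testing.assert_array_equal(t1.folds, t2.folds)
        pd.testing.assert_frame_equal(h1, h2)

    def test_fold_proportions_within_one_record(self, rng):
        for _ in range(50):
            n1 = int(rng.integers(10, 40))
            n0 = int(rng.integers(10, 40))
            y = np.r_[np.ones(n1, int), np.zeros(n0, int)]
            X = pd.DataFrame({"a": np.arange(len(y), dtype=float)})
            folds = int(rng.integers(2, 6))
            train, _, hy = split_data(X, y, 0.8, folds, seed=int(rng.integers(1e6)))
            for cls, n_cls in ((1, n1), (0, n0)):
                expect_hold = (1 - 0.8) * n_cls
                assert abs((hy == cls).sum() - expect_hold) <= 1
                per_fold = [
                    (train.labels[train.folds == f] == cls).sum()
                    for f in range(1, folds + 1)
                ]
                assert max(per_fold) - min(per_fold) <= 1

    def test_single_class_rejected(self):
        X = pd.DataFrame({"a": np.arange(10.0)})
        with pytest.raises(ValueError, match="classes"):
            split_data(X, np.ones(10, int), 0.8, 5, seed=0)


class TestFitBase:
    @pytest.mark.parametrize("learner", ["boosted_trees", "additive_model", "maxent_like"])
    def test_separable_data_perfect_auroc(self, learner):
        X, y = _toy_separable()
        fit = fit_base(learner, X, y, random_state=1)
        Xh, yh = _toy_separable(seed=99)
        assert auroc(fit.predict(Xh), yh) == 1.0
        p = fit.predict(Xh)
        assert p.min() >= 0.0 and p.max() <= 1.0

    @pytest.mark.parametrize("learner", ["boosted_trees", "additive_model", "maxent_like"])
    def test_permuted_labels_near_chance(self, learner):
        rng = np.random.default_rng(0)
        aucs = []
        for seed in range(20):
            X = pd.DataFrame(rng.normal(size=(80, 3)), columns=["a", "b", "c"])
            y = rng.permutation(np.r_[np.ones(40, int), np.zeros(40, int)])
            Xh = pd.DataFrame(rng.normal(size=(60, 3)), columns=["a", "b", "c"])
            yh = np.r_[np.ones(30, int), np.zeros(30, int)]
            fit = fit_base(learner, X, y, random_state=seed)
            aucs.append(auroc(fit.predict(Xh), yh))
        assert abs(np.mean(aucs) - 0.5) < 0.1

    @pytest.mark.parametrize("learner", ["additive_model", "maxent_like"])
    def test_monotone_effect_preserved(self, learner):
        rng = np.random.default_rng(3)
        x = rng.uniform(-2, 2, 300)
        y = (rng.uniform(size=300) < 1 / (1 + np.exp(-3 * x))).astype(int)
        X = pd.DataFrame({"a": x})
        fit = fit_base(learner, X, y, random_state=0)
        probe = pd.DataFrame({"a": np.linspace(-1.5, 1.5, 15)})
        p = fit.predict(probe)
        # monotone up to small boundary wiggle of the unconstrained splines
        assert np.all(np.diff(p) > -0.01)
        assert p[-1] - p[0] > 0.5


class TestAuroc:
    def test_separated_scores(self):
        assert auroc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_all_ties_half(self):
        assert auroc([0.5] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_six_scores_with_tie_matches_all_pairs(self):
        scores = np.array([0.1, 0.4, 0.4, 0.6, 0.7, 0.2])
        labels = np.array([0, 0, 1, 1, 1, 0])
        total = 0.0
        for sp in scores[labels == 1]:
            for sn in scores[labels == 0]:
                total += 1.0 if sp > sn else 0.5 if sp == sn else 0.0
        assert auroc(scores, labels) == pytest.approx(total / 9)

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(st.data())
    def test_equals_mann_whitney_enumeration(self, data):
        n = data.draw(st.integers(4, 30))
        scores = np.array(data.draw(
            st.lists(st.integers(0, 8), min_size=n, max_size=n)
        ), dtype=float)
        labels = np.array(data.draw(
            st.lists(st.integers(0, 1), min_size=n, max_size=n)
        ))
        if labels.sum() in (0, n):
            labels[0], labels[-1] = 0, 1
        pairs = [
            1.0 if sp > sn else 0.5 if sp == sn else 0.0
            for sp in scores[labels == 1]
            for sn in scores[labels == 0]
        ]
        assert auroc(scores, labels) == pytest.approx(np.mean(pairs))

    def test_one_class_absent(self):
        with pytest.raises(UndefinedMetricError):
            auroc([0.1, 0.9], [1, 1])


class TestTss:
    def test_perfect_classification(self):
        assert tss(50, 0, 50, 0).tss == 1.0

    def test_total_misclassification(self):
        assert tss(0, 50, 0, 50).tss == -1.0

    def test_mixed_counts(self):
        res = tss(30, 20, 40, 10)
        assert res.sensitivity == pytest.approx(0.75)
        assert res.specificity == pytest.approx(2 / 3)
        assert res.tss == pytest.approx(0.75 + 2 / 3 - 1)

    def test_empty_margin_rejected(self):
        with pytest.raises(UndefinedMetricError):
            tss(0, 5, 5, 0)


class TestOptimizeCutpoint:
    def test_separable_returns_lowest_presence_score(self):
        res = optimize_cutpoint([0.1, 0.2, 0.7, 0.9], [0, 0, 1, 1])
        assert res.cutpoint == 0.7 and res.tss == 1.0

    def test_degenerate_single_candidate(self):
        res = optimize_cutpoint([0.4] * 4, [0, 1, 0, 1])
        assert res.cutpoint == 0.4

    def test_matches_exhaustive_scan(self, rng):
        for _ in range(20):
            scores = rng.choice(np.linspace(0, 1, 7), size=20)
            labels = rng.integers(0, 2, size=20)
            if labels.sum() in (0, 20):
                labels[0], labels[-1] = 0, 1
            best_tss = -2.0
            for t in np.unique(scores):
                pred = scores >= t
                sens = (pred & (labels == 1)).sum() / (labels == 1).sum()
                spec = (~pred & (labels == 0)).sum() / (labels == 0).sum()
                best_tss = max(best_tss, sens + spec - 1)
            assert optimize_cutpoint(scores, labels).tss == pytest.approx(best_tss)

    def test_no_user_threshold_beats_it(self, rng):
        scores = rng.uniform(size=50)
        labels = rng.integers(0, 2, size=50)
        labels[0], labels[-1] = 0, 1
        best = optimize_cutpoint(scores, labels).tss
        for t in rng.uniform(size=25):
            pred = scores >= t
            sens = (pred & (labels == 1)).sum() / (labels == 1).sum()
            spec = (~pred & (labels == 0)).sum() / (labels == 0).sum()
            assert sens + spec - 1 <= best + 1e-12


class _ConstFit(BaseFit):
    """Stub fit returning a fixed probability (for ensemble arithmetic)."""

    def __init__(self, p, predictors=("a",)):
        super().__init__("boosted_trees", 0, 0, list(predictors), model=None)
        self._p = p

    def predict(self, X):
        return np.full(len(X), self._p)


def _eval(tss_val, auc_val):
    return EvalResult(tss=tss_val, auroc=auc_val, cutpoint=0.5, sensitivity=1, specificity=tss_val)


class TestBuildEnsemble:
    def test_equal_scores_equal_weights(self):
        fits = [_ConstFit(0.3), _ConstFit(0.6)]
        model = build_ensemble(fits, [_eval(0.5, 0.8), _eval(0.5, 0.8)])
        np.testing.assert_allclose(model.weights, [0.5, 0.5])

    def test_tss_gate_is_inclusive_auc_gate_strict(self):
        fits = [_ConstFit(0.2), _ConstFit(0.4), _ConstFit(0.6), _ConstFit(0.8)]
        evals = [_eval(0.39, 0.9), _eval(0.40, 0.9), _eval(0.9, 0.7), _eval(0.9, 0.71)]
        model = build_ensemble(fits, evals)
        kept = {f._p for f in model.fits}
        assert kept == {0.4, 0.8}  # 0.39 fails tss>=0.4; auc=0.7 fails auc>0.7

    def test_matches_hand_filtered_weights(self, rng):
        fits, evals = [], []
        for _ in range(12):
            t, a = rng.uniform(-0.2, 1), rng.uniform(0.4, 1)
            fits.append(_ConstFit(rng.uniform()))
            evals.append(_eval(t, a))
        expected = [(f, e) for f, e in zip(fits, evals) if e.tss >= 0.4 and e.auroc > 0.7]
        if not expected:
            evals[0] = _eval(0.6, 0.9)
            expected = [(fits[0], evals[0])]
        model = build_ensemble(fits, evals)
        assert model.fits == [f for f, _ in expected]
        tot = sum(e.tss for _, e in expected)
        np.testing.assert_allclose(model.weights, [e.tss / tot for _, e in expected])

    def test_no_admissible_models_error_lists_scores(self):
        with pytest.raises(NoAdmissibleModelsError, match="tss=0.100"):
            build_ensemble([_ConstFit(0.5)], [_eval(0.1, 0.6)])


class TestPredictEnsemble:
    def test_single_fit_passthrough(self, spec10, rng):
        stack = make_stack(spec10, {"a": rng.normal(size=spec10.shape)})
        model = build_ensemble([_ConstFit(0.37)], [_eval(0.5, 0.8)])
        out = predict_ensemble(model, stack)
        assert np.all(out.values == pytest.approx(0.37))

    def test_equal_weight_mean(self, spec10, rng):
        stack = make_stack(spec10, {"a": rng.normal(size=spec10.shape)})
        model = build_ensemble(
            [_ConstFit(0.2), _ConstFit(0.8)], [_eval(0.5, 0.8), _eval(0.5, 0.8)]
        )
        assert np.all(predict_ensemble(model, stack).values == pytest.approx(0.5))

    def test_weighted_sum_oracle_and_convexity(self, spec10, rng):
        stack = make_stack(spec10, {"a": rng.normal(size=spec10.shape)})
        ps = rng.uniform(size=4)
        tsses = rng.uniform(0.4, 1.0, size=4)
        model = build_ensemble(
            [_ConstFit(p) for p in ps], [_eval(t, 0.9) for t in tsses]
        )
        expected = np.average(ps, weights=tsses / tsses.sum())
        vals = predict_ensemble(model, stack).values
        assert np.all(vals == pytest.approx(expected))
        assert ps.min() - 1e-12 <= expected <= ps.max() + 1e-12

    def test_missing_predictor_named(self, spec10, rng):
        stack = make_stack(spec10, {"b": rng.normal(size=spec10.shape)})
        model = build_ensemble([_ConstFit(0.5)], [_eval(0.5, 0.8)])
        with pytest.raises(KeyError, match="'a'"):
            predict_ensemble(model, stack)

    def test_nodata_propagates(self, spec10, rng):
        vals = rng.normal(size=spec10.shape)
        vals[3, 3] = spec10.nodata
        stack = make_stack(spec10, {"a": vals})
        out = predict_ensemble(
            build_ensemble([_ConstFit(0.4)], [_eval(0.5, 0.8)]), stack
        )
        assert out.values[3, 3] == spec10.nodata


class TestBinarize:
    def test_cutpoint_endpoints(self, spec10, rng):
        suit = Layer(spec10, "s", rng.uniform(size=spec10.shape))
        assert np.all(binarize(suit, 0.0).values == 1.0)
        ones = binarize(suit, 1.0).values
        assert np.array_equal(ones == 1.0, suit.values >= 1.0)

    def test_random_map_matches_scan(self, spec10, rng):
        suit = Layer(spec10, "s", rng.uniform(size=spec10.shape))
        cut = 0.6
        out = binarize(suit, cut)
        for r in range(10):
            for c in range(10):
                assert out.values[r, c] == (1.0 if suit.values[r, c] >= cut else 0.0)


class TestVariableContribution:
    def _informative_model(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame({"signal": rng.normal(size=300), "noise": rng.normal(size=300)})
        y = (X["signal"] > 0).astype(int).to_numpy()
        fit = fit_base("maxent_like", X, y, random_state=0)
        ev = evaluate_fit(fit, X, y)
        return build_ensemble([fit], [ev]), X

    def test_informative_predictor_scores_highest(self):
        model, X = self._informative_model()
        tab = variable_contribution(model, X, reps=3, seed=0).set_index("predictor")
        assert tab.loc["signal", "contribution"] > tab.loc["noise", "contribution"]
        assert tab["contribution_normalized"].sum() == pytest.approx(1.0)

    def test_unused_predictor_scores_zero(self):
        model, X = self._informative_model()
        X2 = X.copy()
        # a column outside the model's predictor list has no channel to act through
        tab = variable_contribution(model, X2, reps=2, seed=0)
        assert set(tab["predictor"]) == {"signal", "noise"}

    def test_deterministic_under_seed(self):
        model, X = self._informative_model()
        a = variable_contribution(model, X, reps=2, seed=5)
        b = variable_contribution(model, X, reps=2, seed=5)
        pd.testing.assert_frame_equal(a, b)
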