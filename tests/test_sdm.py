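import itertools

import numpy as np
import pandas as pd
import pytest

from geosuit.learners import ROSTER, SurfaceRangeEnvelope, fit_learner, sre_predict
from geosuit.sdm import (
    EvaluationResult,
    GateFailureError,
    auc_score,
    build_ensemble,
    build_training_table,
    confusion_rates,
    evaluate,
    generate_pseudoabsences,
    make_folds,
    predict_map,
    response_curve,
    variable_importance,
)
from geosuit.synthland import sample_occurrences


def brute_force_auc(scores, labels):
    """Enumerate all presence-absence pairs; ties count one half."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0
               for p, n in itertools.product(pos, neg))
    return wins / (len(pos) * len(neg))


class TestEvaluate:
    def test_small_enumeration_case(self):
        scores = [0.9, 0.8, 0.7, 0.85]
        labels = [1, 1, 0, 0]
        ev = evaluate(scores, labels)
        assert ev.auc == pytest.approx(0.75)

    def test_perfect_separation(self):
        ev = evaluate([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert ev.auc == 1.0
        assert ev.tss == pytest.approx(1.0)

    def test_tss_is_sens_plus_spec_minus_one(self, rng):
        scores = rng.random(60)
        labels = rng.integers(0, 2, 60)
        labels[:2] = [0, 1]
        ev = evaluate(scores, labels)
        assert ev.tss == pytest.approx(ev.sensitivity + ev.specificity - 1)

    def test_auc_matches_pairwise_enumeration_with_ties(self, rng):
        for _ in range(25):
            n = int(rng.integers(6, 25))
            scores = rng.integers(0, 5, n) / 4.0  # heavy ties
            labels = rng.integers(0, 2, n)
            if len(np.unique(labels)) < 2:
                continue
            assert auc_score(scores, labels) == pytest.approx(
                brute_force_auc(scores, labels), abs=1e-12
            )

    def test_threshold_matches_exhaustive_scan(self, rng):
        for _ in range(25):
            n = int(rng.integers(8, 40))
            scores = rng.random(n).round(2)
            labels = rng.integers(0, 2, n)
            if len(np.unique(labels)) < 2:
                continue
            ev = evaluate(scores, labels)
            best = max(
                (confusion_rates(scores, labels, t)[0]
                 + confusion_rates(scores, labels, t)[1] - 1, -t)
                for t in np.unique(scores)
            )
            assert ev.tss == pytest.approx(best[0], abs=1e-12)
            assert ev.threshold == pytest.approx(-best[1])

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            evaluate([0.1, 0.2], [1, 1])


class TestFolds:
    def test_balanced_fold_sizes(self):
        labels = np.repeat([0, 1], 50)
        reps = make_folds(labels, k=10, repetitions=1, holdout=0.2, seed=0)
        rep = reps[0]
        assert len(rep["train_idx"]) == 80
        assert len(rep["test_idx"]) == 20
        val_sizes = [len(val) for _, val in rep["cv_folds"]]
        assert val_sizes == [8] * 10
        # every training row validates exactly once
        all_val = np.concatenate([val for _, val in rep["cv_folds"]])
        assert sorted(all_val) == sorted(rep["train_idx"])

    def test_k_one_rejected(self):
        with pytest.raises(ValueError):
            make_folds(np.repeat([0, 1], 50), k=1)

    def test_too_small_class_rejected(self):
        labels = np.array([1] * 5 + [0] * 100)
        with pytest.raises(ValueError):
            make_folds(labels, k=10)

    def test_repetitions_differ_but_sizes_match(self):
        labels = np.repeat([0, 1], 50)
        reps = make_folds(labels, k=5, repetitions=2, seed=3)
        assert len(reps) == 2
        assert not np.array_equal(np.sort(reps[0]["test_idx"]), np.sort(reps[1]["test_idx"]))
        assert len(reps[0]["test_idx"]) == len(reps[1]["test_idx"])


class TestPseudoAbsences:
    def test_no_overlap_with_presences(self, stack40, p_field):
        occ = sample_occurrences(p_field, stack40, 100, seed=1)
        pa = generate_pseudoabsences(stack40, occ, n=500, seed=2)
        assert len(pa) == 500
        grid = stack40.grid
        pres = set(zip(*grid.cell_of(occ["lon"].to_numpy(), occ["lat"].to_numpy())))
        back = set(zip(*grid.cell_of(pa["lon"].to_numpy(), pa["lat"].to_numpy())))
        assert not pres & back

    def test_exhaustive_draw(self, stack40, p_field):
        occ = sample_occurrences(p_field, stack40, 100, seed=1)
        free = int(stack40.mask.sum()) - 100
        pa = generate_pseudoabsences(stack40, occ, n=free, seed=2)
        grid = stack40.grid
        cells = set(zip(*grid.cell_of(pa["lon"].to_numpy(), pa["lat"].to_numpy())))
        assert len(cells) == free
        with pytest.raises(ValueError):
            generate_pseudoabsences(stack40, occ, n=free + 1, seed=2)

    def test_same_seed_identical(self, stack40, p_field):
        occ = sample_occurrences(p_field, stack40, 100, seed=1)
        a = generate_pseudoabsences(stack40, occ, n=50, seed=9)
        b = generate_pseudoabsences(stack40, occ, n=50, seed=9)
        assert a.equals(b)


@pytest.fixture(scope="module")
def toy():
    rng = np.random.default_rng(5)
    n = 120
    x1 = rng.standard_normal(n)
    x2 = rng.standard_normal(n)
    y = (x1 + 0.3 * x2 > 0).astype(int)
    return pd.DataFrame({"x1": x1, "x2": x2}), y


class TestLearners:
    def test_separable_case_glm_perfect(self, toy):
        X, y = toy
        learner = fit_learner("GLM", X, y, seed=0)
        acc = ((learner.predict_proba(X) >= 0.5).astype(int) == y).mean()
        assert acc == 1.0

    @pytest.mark.parametrize("kind", [k for k in ROSTER if k != "SRE"])
    def test_roster_fits_and_is_deterministic(self, toy, kind):
        X, y = toy
        a = fit_learner(kind, X, y, seed=3).predict_proba(X)
        b = fit_learner(kind, X, y, seed=3).predict_proba(X)
        assert np.array_equal(a, b)
        assert np.all((a >= 0) & (a <= 1))
        assert auc_score(a, y) > 0.8

    def test_unknown_learner_rejected(self, toy):
        with pytest.raises(ValueError, match="unknown learner"):
            fit_learner("CNN", *toy, seed=0)

    def test_single_class_rejected(self, toy):
        X, _ = toy
        with pytest.raises(ValueError, match="single-class"):
            fit_learner("GLM", X, np.ones(len(X), int), seed=0)

    def test_sre_median_presence_inside_envelope(self, toy):
        X, y = toy
        sre = SurfaceRangeEnvelope(quantile=0.025).fit(X, y)
        median = X[y == 1].median()
        assert sre_predict(sre.bounds_, median) == 1.0

    def test_sre_outside_bound_is_zero(self, toy):
        X, y = toy
        sre = SurfaceRangeEnvelope().fit(X, y)
        row = X[y == 1].median()
        row["x1"] = sre.bounds_["x1"][1] + 1.0
        assert sre_predict(sre.bounds_, row) == 0.0

    def test_sre_q0_contains_all_training_presences(self, toy):
        X, y = toy
        sre = SurfaceRangeEnvelope(quantile=0.0).fit(X, y)
        preds = sre.predict_proba_presence(X[y == 1])
        assert np.all(preds == 1.0)


class ConstModel:
    def __init__(self, value, columns=("x1", "x2")):
        self.value = value
        self.columns = tuple(columns)
        self.kind = f"const{value}"

    def predict_proba(self, X):
        return np.full(len(X), self.value)


def const_candidate(value, auc=0.99, tss=0.95):
    ev = EvaluationResult(sensitivity=0.9, specificity=tss + 1 - 0.9, tss=tss,
                          auc=auc, threshold=0.5)
    return (ConstModel(value), ev)


class TestEnsemble:
    def test_single_survivor_weight_one(self):
        ens = build_ensemble([const_candidate(0.3)])
        assert list(ens.weights.values()) == [1.0]
        assert np.allclose(ens.predict_proba(pd.DataFrame({"x1": [0], "x2": [0]})), 0.3)

    def test_equal_tss_equal_weights_mean(self):
        ens = build_ensemble([const_candidate(0.2), const_candidate(0.4)])
        p = ens.predict_proba(pd.DataFrame({"x1": [0], "x2": [0]}))
        assert p[0] == pytest.approx(0.3)

    def test_gate_is_strict(self):
        good = const_candidate(0.5, auc=0.95, tss=0.85)
        borderline = const_candidate(0.9, auc=0.95, tss=0.79)
        at_gate = const_candidate(0.9, auc=0.9, tss=0.85)
        ens = build_ensemble([good, borderline, at_gate])
        assert len(ens.members) == 1

    def test_all_fail_raises_with_metrics(self):
        with pytest.raises(GateFailureError, match="candidate metrics"):
            build_ensemble([const_candidate(0.5, auc=0.85, tss=0.5)])

    def test_invariant_under_member_duplication(self, rng):
        X = pd.DataFrame(rng.standard_normal((20, 2)), columns=["x1", "x2"])
        a, b = ConstModel(0.2), ConstModel(0.6)
        from geosuit.sdm import EnsembleModel
        whole = EnsembleModel([("a", a, 0.5), ("b", b, 0.5)])
        split = EnsembleModel([("a", a, 0.5), ("b1", b, 0.25), ("b2", b, 0.25)])
        assert np.allclose(whole.predict_proba(X), split.predict_proba(X))


class TestMapInterpretation:
    def test_constant_half_maps_to_500(self, stack40):
        from geosuit.sdm import EnsembleModel
        ens = EnsembleModel([("c", ConstModel(0.5, columns=stack40.names), 1.0)])
        smap = predict_map(ens, stack40)
        assert np.all(smap.values[stack40.mask] == 500)

    def test_bounds_map_to_0_and_1000(self, stack40):
        from geosuit.sdm import EnsembleModel
        for v, expected in ((0.0, 0), (1.0, 1000)):
            ens = EnsembleModel([("c", ConstModel(v, columns=stack40.names), 1.0)])
            assert np.all(predict_map(ens, stack40).values[stack40.mask] == expected)

    def test_ensemble_between_member_extremes(self, stack40):
        from geosuit.sdm import EnsembleModel
        lo, hi = 0.2, 0.8
        ens = EnsembleModel([
            ("lo", ConstModel(lo, columns=stack40.names), 0.25),
            ("hi", ConstModel(hi, columns=stack40.names), 0.75),
        ])
        vals = predict_map(ens, stack40).values[stack40.mask]
        assert np.all(vals >= 1000 * lo) and np.all(vals <= 1000 * hi)

    def test_missing_layer_rejected(self, stack40):
        from geosuit.sdm import EnsembleModel
        ens = EnsembleModel([("c", ConstModel(0.5, columns=("ghost",)), 1.0)])
        with pytest.raises(KeyError, match="ghost"):
            predict_map(ens, stack40)

    def test_importance_zero_coefficient_near_zero(self, rng):
        X = pd.DataFrame(rng.standard_normal((300, 3)), columns=["a", "b", "c"])
        y = (X["a"] + 0.2 * rng.standard_normal(300) > 0).astype(int)
        learner = fit_learner("GLM", X, y, seed=0)
        imp = variable_importance(learner, X, n_perm=4, seed=1)
        assert imp["a"] > 0.2
        assert imp["b"] == pytest.approx(0.0, abs=0.02)
        assert imp["c"] == pytest.approx(0.0, abs=0.02)

    def test_importance_matches_direct_recomputation(self, rng):
        X = pd.DataFrame(rng.standard_normal((50, 2)), columns=["a", "b"])
        y = (X["a"] > 0).astype(int)
        learner = fit_learner("GLM", X, y, seed=0)
        imp = variable_importance(learner, X, n_perm=1, seed=42)
        base = learner.predict_proba(X)
        rng2 = np.random.default_rng(42)
        shuffled = X.copy()
        shuffled["a"] = rng2.permutation(shuffled["a"].to_numpy())
        expected = 1 - np.corrcoef(base, learner.predict_proba(shuffled))[0, 1]
        assert imp["a"] == pytest.approx(np.clip(expected, 0, 1))

    def test_importance_deterministic(self, rng):
        X = pd.DataFrame(rng.standard_normal((60, 2)), columns=["a", "b"])
        y = (X["a"] > 0).astype(int)
        learner = fit_learner("GLM", X, y, seed=0)
        a = variable_importance(learner, X, n_perm=2, seed=5)
        b = variable_importance(learner, X, n_perm=2, seed=5)
        assert a.equals(b)

    def test_constant_model_importance_zero(self, rng, caplog):
        X = pd.DataFrame(rng.standard_normal((20, 2)), columns=["a", "b"])
        with caplog.at_level("WARNING"):
            imp = variable_importance(ConstModel(0.4), X, n_perm=2, seed=0)
        assert np.all(imp == 0.0)

    def test_response_curve_flat_for_constant_model(self, rng):
        X = pd.DataFrame(rng.standard_normal((30, 2)), columns=["x1", "x2"])
        curve = response_curve(ConstModel(0.7), "x1", X, n_points=11)
        assert np.all(curve["probability"] == 0.7)
        assert curve["value"].iloc[0] == X["x1"].min()
        assert curve["value"].iloc[-1] == X["x1"].max()

    def test_response_curve_monotone_for_positive_logit(self, rng):
        X = pd.DataFrame(rng.standard_normal((200, 2)), columns=["a", "b"])
        y = (X["a"] + 0.1 * rng.standard_normal(200) > 0).astype(int)
        learner = fit_learner("GLM", X, y, seed=0)
        curve = response_curve(learner, "a", X, n_points=20)
        assert np.all(np.diff(curve["probability"]) >= 0)

    def test_response_curve_unknown_variable(self, rng):
        X = pd.DataFrame(rng.standard_normal((10, 1)), columns=["a"])
        with pytest.raises(KeyError):
            response_curve(ConstModel(0.5), "ghost", X)


class TestTrainingTable:
    def test_labels_and_rows(self, stack40, p_field):
        occ = sample_occurrences(p_field, stack40, 80, seed=1)
        pa = generate_pseudoabsences(stack40, occ, n=160, seed=2)
        X, y = build_training_table(stack40, occ, pa)
        assert len(X) == 240
        assert y.sum() == 80
        assert list(X.columns) == stack40.names
        assert not X.isna().any().any()
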