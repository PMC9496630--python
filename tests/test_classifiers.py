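"""Seven model kinds: grid-search training, confidence contract, PLS-DA."""

import numpy as np
import pandas as pd
import pytest

from emlscreen import (
    MODEL_KINDS,
    PLSDAClassifier,
    TrainedModel,
    admit_models,
    log_and_autoscale,
    normalize_to_is,
    plsda_diagnostics,
    predict_confidence,
    train_model,
)
from emlscreen.classifiers import _cv_scores, make_estimator
from emlscreen.peaktable import CTRL, EC
from emlscreen.preprocess import ProcessedMatrix

from conftest import make_table


@pytest.fixture(scope="module")
def separable_matrix(small_cohort):
    return log_and_autoscale(normalize_to_is(small_cohort))


class _FixedProba:
    """Stub estimator returning a constant p(EC)."""

    def __init__(self, p):
        self.p = p

    def predict_proba(self, X):
        return np.tile([1 - self.p, self.p], (len(X), 1))


def _stub_model(p=0.8, cv_accuracy=0.9, cv_auc=0.95, train_accuracy=0.95):
    return TrainedModel(
        kind="NB",
        features=["f0"],
        estimator=_FixedProba(p),
        params={},
        cv_accuracy=cv_accuracy,
        cv_auc=cv_auc,
        train_accuracy=train_accuracy,
        folds=5,
        seed=0,
    )


class TestTrainModel:
    @pytest.mark.parametrize("kind", MODEL_KINDS)
    def test_separable_cohort_trains_every_kind(self, separable_matrix, kind):
        m = train_model(kind, separable_matrix, separable_matrix.labels, folds=5, seed=0)
        assert m.cv_accuracy > 0.9
        assert m.cv_auc > 0.95
        assert 0 <= m.train_accuracy <= 1

    def test_single_point_grid_equals_plain_cv(self, separable_matrix):
        grid = {"max_depth": [3]}
        m = train_model("DT", separable_matrix, separable_matrix.labels,
                        grid=grid, folds=5, seed=1)
        assert m.params == {"max_depth": 3}
        acc, auc = _cv_scores(
            make_estimator("DT", seed=1, max_depth=3),
            separable_matrix.X.to_numpy(),
            (separable_matrix.labels == EC).astype(int).to_numpy(),
            5, 1,
        )
        assert m.cv_accuracy == pytest.approx(acc)
        assert m.cv_auc == pytest.approx(auc)

    def test_winner_beats_every_grid_point(self, separable_matrix):
        grid = {"max_depth": [1, 2, 4], "min_samples_leaf": [1, 3]}
        m = train_model("DT", separable_matrix, separable_matrix.labels,
                        grid=grid, folds=5, seed=2)
        X = separable_matrix.X.to_numpy()
        y = (separable_matrix.labels == EC).astype(int).to_numpy()
        from sklearn.model_selection import ParameterGrid
        for params in ParameterGrid(grid):
            acc, _ = _cv_scores(make_estimator("DT", seed=2, **params), X, y, 5, 2)
            assert m.cv_accuracy >= acc - 1e-12

    def test_deterministic_for_fixed_seed(self, separable_matrix):
        a = train_model("RF", separable_matrix, separable_matrix.labels, folds=5, seed=3)
        b = train_model("RF", separable_matrix, separable_matrix.labels, folds=5, seed=3)
        assert a.cv_accuracy == b.cv_accuracy
        assert a.params == b.params

    def test_degenerate_inputs_rejected(self, separable_matrix):
        with pytest.raises(ValueError, match="grid"):
            train_model(
                "DT", separable_matrix, separable_matrix.labels, grid={"max_depth": []}
            )
        ec_only = separable_matrix.labels.copy()
        ec_only[:] = EC
        with pytest.raises(ValueError, match="classes"):
            train_model("DT", separable_matrix, ec_only, folds=5)


class TestPredictConfidence:
    def test_boundary_probability_gives_zero_confidence(self):
        label, conf = predict_confidence(_stub_model(p=0.5), pd.Series({"f0": 1.0}))
        assert conf == 0.0
        assert label == CTRL  # non-positive convention at the exact boundary

    def test_certain_probability_gives_full_confidence(self):
        label, conf = predict_confidence(_stub_model(p=1.0), pd.Series({"f0": 1.0}))
        assert (label, conf) == (EC, 1.0)

    def test_confidence_is_sign_free(self):
        _, c_pos = predict_confidence(_stub_model(p=0.9), pd.Series({"f0": 1.0}))
        _, c_neg = predict_confidence(_stub_model(p=0.1), pd.Series({"f0": 1.0}))
        assert c_pos == pytest.approx(c_neg)

    def test_missing_feature_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            predict_confidence(_stub_model(), pd.Series({"other": 1.0}))

    def test_plsda_sample_at_centroid_has_confidence_one(self):
        X = np.vstack([np.random.default_rng(0).normal(0, 0.1, (10, 2)),
                       np.tile([5.0, 5.0], (10, 1))])
        y = np.array([0] * 10 + [1] * 10)
        clf = PLSDAClassifier(n_components=1).fit(X, y)
        dec = clf.decision_function(np.array([[5.0, 5.0]]))
        assert dec[0] == pytest.approx(1.0)
        assert clf.predict(np.array([[5.0, 5.0]]))[0] == 1

    def test_plsda_confidence_invariant_to_class_encoding(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(0, 1, (15, 4)), rng.normal(2, 1, (15, 4))])
        y = np.array([0] * 15 + [1] * 15)
        a = PLSDAClassifier(n_components=2).fit(X, y)
        b = PLSDAClassifier(n_components=2).fit(X, 1 - y)
        assert np.allclose(
            np.abs(a.decision_function(X)), np.abs(b.decision_function(X))
        )


class TestAdmitModels:
    def test_gates_are_strict(self):
        at_gate = _stub_model(cv_accuracy=0.65, cv_auc=0.90)
        assert admit_models([at_gate]) == []
        above = _stub_model(cv_accuracy=0.66, cv_auc=0.90, train_accuracy=0.70)
        assert admit_models([above]) == [above]

    def test_both_gates_required(self):
        good_acc = _stub_model(cv_accuracy=0.90, cv_auc=0.80)
        assert admit_models([good_acc]) == []

    def test_overfit_gap_rejected(self):
        overfit = _stub_model(cv_accuracy=0.70, cv_auc=0.90, train_accuracy=1.0)
        assert admit_models([overfit]) == []

    def test_order_preserved(self):
        a = _stub_model(cv_accuracy=0.70, cv_auc=0.90, train_accuracy=0.75)
        b = _stub_model(cv_accuracy=0.80, cv_auc=0.95, train_accuracy=0.85)
        assert admit_models([a, b]) == [a, b]

    def test_admits_all_seven_kinds_on_separated_data(self, separable_matrix):
        models = [
            train_model(k, separable_matrix, separable_matrix.labels, folds=5, seed=0)
            for k in MODEL_KINDS
        ]
        assert [m.kind for m in admit_models(models)] == list(MODEL_KINDS)


@pytest.fixture(scope="module")
def diag(separable_matrix):
    return plsda_diagnostics(
        separable_matrix, separable_matrix.labels,
        max_lv=3, folds=5, n_perm=30, seed=0,
    )


class TestPLSDADiagnostics:

    def test_mean_squared_vip_is_one(self, diag):
        assert float((diag.vip**2).mean()) == pytest.approx(1.0, abs=1e-6)

    def test_q2_not_above_r2(self, diag):
        assert diag.q2 <= diag.r2

    def test_separable_data_is_significant(self, diag):
        assert diag.permutation_p == pytest.approx(1 / 31)
        assert diag.q2 > 0.5

    def test_zero_weight_feature_has_zero_vip(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 5))
        X[:, 4] = 0.0  # carries no variance, gets zero PLS weight
        y = (X[:, 0] > 0).astype(int)
        idx = pd.Index([f"s{i}" for i in range(30)], name="sample_id")
        cols = [f"f{j}" for j in range(5)]
        m = ProcessedMatrix(
            X=pd.DataFrame(X, index=idx, columns=cols),
            labels=pd.Series(np.where(y == 1, EC, CTRL), index=idx),
            feature_means=pd.Series(0.0, index=cols),
            feature_sds=pd.Series(1.0, index=cols),
        )
        diag = plsda_diagnostics(m, m.labels, max_lv=2, folds=3, n_perm=10, seed=0)
        assert diag.vip["f4"] == pytest.approx(0.0, abs=1e-12)

    def test_max_lv_beyond_rank_rejected(self, separable_matrix):
        tiny = separable_matrix.subset_samples(list(separable_matrix.samples[:4]) +
                                               list(separable_matrix.samples[-4:]))
        with pytest.raises(ValueError, match="rank|exceeds"):
            plsda_diagnostics(tiny, tiny.labels, max_lv=20, folds=2, n_perm=5, seed=0)
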