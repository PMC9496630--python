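"""EML score identities, Youden threshold, DeLong AUC, metric panel."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import mannwhitneyu

from emlscreen import (
    Vote,
    choose_threshold,
    delong_auc,
    diagnostic_panel,
    eml_score,
    log_and_autoscale,
    normalize_to_is,
    screen_cohort,
    train_model,
)
from emlscreen.peaktable import CTRL, EC

votes_strategy = st.lists(
    st.builds(
        Vote,
        kind=st.sampled_from(["NB", "GLM", "RF"]),
        label=st.sampled_from([EC, CTRL]),
        confidence=st.floats(0, 1),
        accuracy=st.floats(0, 1),
    ),
    min_size=1,
    max_size=7,
)


class TestEMLScore:
    def test_balanced_votes_score_zero(self):
        w = Vote(kind="NB", label=EC, confidence=0.6, accuracy=0.9)
        against = Vote(kind="GLM", label=CTRL, confidence=0.6, accuracy=0.9)
        assert eml_score([w, against]) == 0.0

    def test_hand_arithmetic(self):
        votes = [
            Vote(kind="NB", label=EC, confidence=0.5, accuracy=0.9),    # +45
            Vote(kind="GLM", label=CTRL, confidence=0.25, accuracy=0.8),  # -20
            Vote(kind="RF", label=EC, confidence=1.0, accuracy=0.7),    # +70
        ]
        assert eml_score(votes) == pytest.approx(95.0)

    def test_seven_unanimous_certain_votes_hit_the_bound(self):
        votes = [
            Vote(kind=k, label=EC, confidence=1.0, accuracy=1.0)
            for k in ("NB", "GLM", "FLM", "DL", "DT", "RF", "PLSDA")
        ]
        assert eml_score(votes) == 700.0

    def test_empty_votes_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            eml_score([])

    @pytest.mark.parametrize(
        "kwargs", [{"confidence": 1.5}, {"accuracy": -0.1}, {"label": "EX"}]
    )
    def test_vote_validation(self, kwargs):
        base = dict(kind="NB", label=EC, confidence=0.5, accuracy=0.5)
        with pytest.raises(ValueError):
            Vote(**{**base, **kwargs})

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(votes_strategy)
    def test_antisymmetry_and_bound(self, votes):
        score = eml_score(votes)
        assert eml_score([v.flipped() for v in votes]) == pytest.approx(-score)
        assert abs(score) <= 100.0 * len(votes) + 1e-9

    def test_vote_sign_matches_label(self):
        assert Vote(kind="NB", label=EC, confidence=1, accuracy=1).sign == 1
        assert Vote(kind="NB", label=CTRL, confidence=1, accuracy=1).sign == -1


def _brute_force_youden(scores, y):
    uniq = np.unique(scores)
    cands = np.concatenate([[-np.inf], (uniq[:-1] + uniq[1:]) / 2, [np.inf]])
    best = (-np.inf, -np.inf, -np.inf)
    for t in cands:
        pred = scores > t
        s = (pred & y).sum() / y.sum()
        sp = (~pred & ~y).sum() / (~y).sum()
        best = max(best, (s + sp - 1, sp, t))
    return best


class TestChooseThreshold:
    def test_four_point_oracle(self):
        th, roc, auc, _ = choose_threshold(
            np.array([1.0, 2, 3, 4]), np.array([CTRL, CTRL, EC, EC])
        )
        assert th == 2.5
        assert auc == 1.0
        assert roc["youden_j"].max() == pytest.approx(1.0)

    def test_perfect_separation_returns_gap_midpoint(self):
        rng = np.random.default_rng(0)
        neg = rng.uniform(0, 1, 30)
        pos = rng.uniform(2, 3, 30)
        scores = np.concatenate([neg, pos])
        labels = np.array([CTRL] * 30 + [EC] * 30)
        th, _, auc, _ = choose_threshold(scores, labels)
        assert neg.max() < th < pos.min()
        assert auc == pytest.approx(1.0)

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            n = rng.integers(10, 200)
            y = rng.random(n) < rng.uniform(0.2, 0.8)
            if y.all() or not y.any():
                continue
            scores = np.round(rng.normal(y.astype(float), 1.0), 2)  # force ties
            th, roc, auc, _ = choose_threshold(
                scores, np.where(y, EC, CTRL)
            )
            j_best, sp_best, t_best = _brute_force_youden(scores, y)
            j_got = roc.loc[roc["threshold"] == th, "youden_j"].iloc[0]
            assert j_got == pytest.approx(j_best)
            assert th == t_best  # same tie-break: higher Sp, then higher cut

    def test_null_scores_have_auc_near_half(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=2000)
        labels = np.where(rng.random(2000) < 0.5, EC, CTRL)
        _, _, auc, ci = choose_threshold(scores, labels)
        assert auc == pytest.approx(0.5, abs=0.05)
        assert ci[0] <= 0.5 <= ci[1]

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            choose_threshold(np.array([1.0, 2.0]), np.array([EC, EC]))


class TestDeLong:
    def test_auc_equals_mann_whitney_u(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            n = int(rng.integers(8, 120))
            y = rng.random(n) < 0.5
            if y.all() or not y.any():
                continue
            scores = np.round(rng.normal(size=n), 1)
            auc, var = delong_auc(scores, y)
            u = mannwhitneyu(scores[y], scores[~y]).statistic
            assert auc == pytest.approx(u / (y.sum() * (~y).sum()))
            assert var >= 0


class TestDiagnosticPanel:
    def test_perfect_predictions(self):
        truth = [EC] * 5 + [CTRL] * 5
        panel = diagnostic_panel(truth, truth)
        assert (panel.sensitivity, panel.specificity) == (1.0, 1.0)
        assert panel.ppv == panel.npv == panel.accuracy == 1.0
        assert panel.nlr == 0.0
        assert panel.plr is None  # Sp = 1 leaves PLR not determinable

    def test_likelihood_ratio_identities_on_random_tables(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            tp, fp, tn, fn = rng.integers(0, 30, size=4)
            if tp + fn == 0 or tn + fp == 0:
                continue
            truth = [EC] * (tp + fn) + [CTRL] * (tn + fp)
            pred = [EC] * tp + [CTRL] * fn + [CTRL] * tn + [EC] * fp
            panel = diagnostic_panel(pred, truth)
            if panel.plr is not None:
                assert panel.plr * (1 - panel.specificity) == pytest.approx(
                    panel.sensitivity
                )
            if panel.nlr is not None:
                assert panel.nlr * panel.specificity == pytest.approx(
                    1 - panel.sensitivity
                )
            assert 0 <= panel.accuracy <= 1

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            diagnostic_panel([EC], [EC, CTRL])

    def test_single_class_truth_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            diagnostic_panel([EC, CTRL], [EC, EC])

    def test_nd_rendering(self):
        truth = [EC] * 3 + [CTRL] * 3
        pred = [EC, EC, CTRL, CTRL, CTRL, CTRL]
        d = diagnostic_panel(pred, truth).as_dict()
        assert d["PLR"] == "ND"  # specificity is 1 here


@pytest.fixture(scope="module")
def fitted(small_cohort):
    matrix = log_and_autoscale(normalize_to_is(small_cohort))
    model = train_model("NB", matrix, matrix.labels, folds=5, seed=0)
    return model, matrix


class TestScreenCohort:

    def test_degenerate_thresholds(self, fitted):
        model, matrix = fitted
        all_ctrl, _ = screen_cohort([model], matrix, threshold=np.inf)
        assert all(r.predicted == CTRL for r in all_ctrl)
        all_ec, _ = screen_cohort([model], matrix, threshold=-np.inf)
        assert all(r.predicted == EC for r in all_ec)

    def test_single_model_ensemble_reduces_to_that_model(self, fitted):
        model, matrix = fitted
        results, _ = screen_cohort([model], matrix, threshold=0.0)
        proba = model.estimator.predict_proba(matrix.X.to_numpy())[:, 1]
        expected = np.where(proba > 0.5, EC, CTRL)
        assert [r.predicted for r in results] == list(expected)

    def test_class_summary_error_rates(self, fitted):
        model, matrix = fitted
        results, summary = screen_cohort([model], matrix, threshold=0.0)
        df = pd.DataFrame(
            {"truth": matrix.labels.to_numpy(), "pred": [r.predicted for r in results]}
        )
        ec_err = (df[df.truth == EC].pred != EC).mean()
        assert summary.loc[EC, "error_rate"] == pytest.approx(ec_err)
        assert summary.loc[EC, "N"] == (matrix.labels == EC).sum()

    def test_empty_model_list_rejected(self, fitted):
        _, matrix = fitted
        with pytest.raises(ValueError, match="empty model list"):
            screen_cohort([], matrix)
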