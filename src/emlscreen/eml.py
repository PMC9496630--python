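"""Ensemble machine-learning (EML) score, threshold choice and metric panel.

Each admitted classifier casts one vote per sample: its predicted class
mapped to a sign (+1 for EC, -1 for CTRL) times a weight equal to the
model's cross-validation accuracy times its prediction confidence, on a
scale of 100. The EML score is the sum of the signed votes, so a sample for
which predictions for and against EC are equal in number and weight scores
exactly 0; a score above the decision threshold screens positive for EC.

The threshold is the Youden-index-optimal ROC cut (maximizing
sensitivity + specificity - 1); the AUC and its 95% CI follow DeLong's
covariance estimator. The diagnostic panel reports sensitivity,
specificity, likelihood ratios, predictive values and accuracy, flagging
ratios with zero denominators as not determinable (ND).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classifiers import TrainedModel, _confidences
from .peaktable import CTRL, EC
from .preprocess import ProcessedMatrix

#: Per-model vote scale. With seven models the EML score is bounded by
#: +/- 700; observed cohort scores live in the hundreds.
VOTE_SCALE = 100.0


@dataclass(frozen=True)
class Vote:
    """One model's signed, weighted vote for a single sample."""

    kind: str
    label: str
    confidence: float
    accuracy: float
    scale: float = VOTE_SCALE

    def __post_init__(self) -> None:
        if not 0 <= self.confidence <= 1:
            raise ValueError(f"confidence must be in [0, 1], got {self.confidence}")
        if not 0 <= self.accuracy <= 1:
            raise ValueError(f"accuracy must be in [0, 1], got {self.accuracy}")
        if self.label not in (EC, CTRL):
            raise ValueError(f"label must be {EC!r} or {CTRL!r}, got {self.label!r}")

    @property
    def sign(self) -> int:
        return 1 if self.label == EC else -1

    @property
    def signed_vote(self) -> float:
        return self.sign * self.scale * self.accuracy * self.confidence

    def flipped(self) -> "Vote":
        return Vote(
            kind=self.kind,
            label=CTRL if self.label == EC else EC,
            confidence=self.confidence,
            accuracy=self.accuracy,
            scale=self.scale,
        )


def eml_score(votes: list[Vote]) -> float:
    """Sum the signed weighted votes into the per-sample EML score."""
    if not votes:
        raise ValueError("empty vote list")
    return float(sum(v.signed_vote for v in votes))


def make_votes(
    models: list[TrainedModel], X: pd.DataFrame, scale: float = VOTE_SCALE
) -> list[list[Vote]]:
    """Per-sample vote lists for a block of preprocessed samples."""
    per_model = []
    for m in models:
        labels, confs = _confidences(m, X)
        per_model.append((m, labels, confs))
    out = []
    for i in range(len(X)):
        out.append(
            [
                Vote(
                    kind=m.kind,
                    label=str(labels[i]),
                    confidence=float(confs[i]),
                    accuracy=m.cv_accuracy,
                    scale=scale,
                )
                for m, labels, confs in per_model
            ]
        )
    return out


# --------------------------------------------------------------- DeLong AUC


def _midrank(x: np.ndarray) -> np.ndarray:
    order = np.argsort(x, kind="mergesort")
    xs = x[order]
    n = len(x)
    mid = np.empty(n, dtype=float)
    i = 0
    while i < n:
        j = i
        while j < n and xs[j] == xs[i]:
            j += 1
        mid[i:j] = 0.5 * (i + j - 1) + 1
        i = j
    out = np.empty(n, dtype=float)
    out[order] = mid
    return out


def delong_auc(scores: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """AUC and its DeLong variance via the structural-components estimator.

    The point estimate equals the Mann-Whitney U statistic divided by
    (n_pos * n_neg).
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y).astype(bool)
    pos, neg = scores[y], scores[~y]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    tz = _midrank(np.concatenate([pos, neg]))
    tx = _midrank(pos)
    ty = _midrank(neg)
    auc = tz[:m].sum() / (m * n) - (m + 1.0) / (2.0 * n)
    v01 = (tz[:m] - tx) / n            # components over positives
    v10 = 1.0 - (tz[m:] - ty) / m      # components over negatives
    s01 = v01.var(ddof=1) if m > 1 else 0.0
    s10 = v10.var(ddof=1) if n > 1 else 0.0
    return float(auc), float(s01 / m + s10 / n)


def delong_ci(
    scores: np.ndarray, y: np.ndarray, level: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """DeLong AUC with a confidence interval on the logit scale.

    The logit transform keeps the interval inside (0, 1); degenerate cases
    (AUC of exactly 0 or 1, or zero variance) fall back to a clipped linear
    interval.
    """
    from scipy.stats import norm

    auc, var = delong_auc(scores, y)
    se = math.sqrt(max(var, 0.0))
    z = norm.ppf(0.5 + level / 2.0)
    if se == 0.0:
        return auc, (auc, auc)
    if 0.0 < auc < 1.0:
        logit = math.log(auc / (1.0 - auc))
        se_logit = se / (auc * (1.0 - auc))
        lo = 1.0 / (1.0 + math.exp(-(logit - z * se_logit)))
        hi = 1.0 / (1.0 + math.exp(-(logit + z * se_logit)))
    else:
        lo = max(0.0, auc - z * se)
        hi = min(1.0, auc + z * se)
    return auc, (lo, hi)


# --------------------------------------------------------- Youden threshold


def _sens_spec(scores: np.ndarray, y: np.ndarray, threshold: float) -> tuple[float, float]:
    pred_pos = scores > threshold
    tp = int(np.sum(pred_pos & y))
    fn = int(np.sum(~pred_pos & y))
    tn = int(np.sum(~pred_pos & ~y))
    fp = int(np.sum(pred_pos & ~y))
    s = tp / (tp + fn)
    sp = tn / (tn + fp)
    return s, sp


def choose_threshold(
    scores, labels
) -> tuple[float, pd.DataFrame, float, tuple[float, float]]:
    """Youden-optimal decision threshold with ROC, DeLong AUC and 95% CI.

    Candidate cuts are the midpoints between consecutive sorted unique
    scores plus -inf and +inf (invariant under monotone rescaling of the
    scores); the returned cut maximizes J = sensitivity + specificity - 1,
    with ties broken toward higher specificity and then the higher cut.
    Classification is positive (EC) strictly above the threshold.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(pd.Series(labels) == EC) if not isinstance(labels, np.ndarray) else (
        np.asarray(labels) == EC
    )
    y = np.asarray(y, dtype=bool)
    if y.all() or not y.any():
        raise ValueError("both classes must be present to choose a threshold")

    uniq = np.unique(scores)
    cands = np.concatenate([[-np.inf], (uniq[:-1] + uniq[1:]) / 2.0, [np.inf]])
    rows = []
    best = None
    for t in cands:
        s, sp = _sens_spec(scores, y, t)
        j = s + sp - 1.0
        rows.append((t, s, sp, j))
        key = (j, sp, t)
        if best is None or key > best[0]:
            best = (key, t)
    roc = pd.DataFrame(rows, columns=["threshold", "sensitivity", "specificity", "youden_j"])
    auc, ci = delong_ci(scores, y)
    return float(best[1]), roc, auc, ci


# ---------------------------------------------------------- metric panel


@dataclass
class DiagnosticPanel:
    """Confusion counts and the derived screening metrics.

    Ratios with a zero denominator are ``None`` and render as "ND"
    (not determinable).
    """

    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    plr: float | None
    nlr: float | None
    ppv: float | None
    npv: float | None
    accuracy: float
    auc: float | None = None
    auc_ci: tuple[float, float] | None = None

    def as_dict(self) -> dict:
        nd = lambda v: "ND" if v is None else v
        return {
            "TP": self.tp, "FP": self.fp, "TN": self.tn, "FN": self.fn,
            "S": self.sensitivity, "Sp": self.specificity,
            "PLR": nd(self.plr), "NLR": nd(self.nlr),
            "PPV": nd(self.ppv), "NPV": nd(self.npv),
            "A": self.accuracy,
            "AUC": nd(self.auc),
            "AUC_CI": self.auc_ci,
        }


def diagnostic_panel(
    predictions, truth, scores=None
) -> DiagnosticPanel:
    """Sensitivity, specificity, likelihood ratios, predictive values, accuracy.

    S = TP/(TP+FN), Sp = TN/(TN+FP), PLR = S/(1-Sp), NLR = (1-S)/Sp,
    PPV = TP/(TP+FP), NPV = TN/(TN+FN), A = (TP+TN)/total. When `scores`
    are given, the AUC and its DeLong 95% CI are included.
    """
    pred = np.asarray(pd.Series(predictions) == EC, dtype=bool)
    y = np.asarray(pd.Series(truth) == EC, dtype=bool)
    if len(pred) != len(y):
        raise ValueError("predictions and truth have different lengths")
    if y.all() or not y.any():
        raise ValueError("both classes must be present in truth")

    tp = int(np.sum(pred & y))
    fp = int(np.sum(pred & ~y))
    tn = int(np.sum(~pred & ~y))
    fn = int(np.sum(~pred & y))
    s = tp / (tp + fn)
    sp = tn / (tn + fp)
    ratio = lambda num, den: None if den == 0 else num / den
    auc, ci = (None, None)
    if scores is not None:
        auc, ci = delong_ci(np.asarray(scores, dtype=float), y)
    return DiagnosticPanel(
        tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=s,
        specificity=sp,
        plr=ratio(s, 1.0 - sp),
        nlr=ratio(1.0 - s, sp),
        ppv=ratio(tp, tp + fp),
        npv=ratio(tn, tn + fn),
        accuracy=(tp + tn) / len(y),
        auc=auc,
        auc_ci=ci,
    )


# ---------------------------------------------------------- cohort screening


@dataclass
class EMLResult:
    """Per-sample ensemble outcome: votes, score and screening decision."""

    sample_id: str
    votes: list[Vote]
    score: float
    threshold: float

    @property
    def predicted(self) -> str:
        return EC if self.score > self.threshold else CTRL


def screen_cohort(
    models: list[TrainedModel],
    matrix: ProcessedMatrix,
    threshold: float = 0.0,
    scale: float = VOTE_SCALE,
) -> tuple[list[EMLResult], pd.DataFrame]:
    """Score every sample with the ensemble and summarize per true class.

    Returns the per-sample results and a summary table in the style of a
    per-class scorecard: N, mean +/- sd, min, max and the classification
    error rate (for the EC class, the fraction screened negative; for every
    other class, the fraction screened positive).
    """
    if not models:
        raise ValueError("empty model list")
    votes_per_sample = make_votes(models, matrix.X, scale=scale)
    results = [
        EMLResult(
            sample_id=str(sid),
            votes=votes,
            score=eml_score(votes),
            threshold=threshold,
        )
        for sid, votes in zip(matrix.samples, votes_per_sample)
    ]

    df = pd.DataFrame(
        {
            "true_class": matrix.labels.to_numpy(),
            "score": [r.score for r in results],
            "predicted": [r.predicted for r in results],
        },
        index=matrix.samples,
    )
    rows = []
    for cls, grp in df.groupby("true_class", sort=True):
        wrong = (
            (grp["predicted"] != EC) if cls == EC else (grp["predicted"] == EC)
        ).mean()
        rows.append(
            {
                "class": cls,
                "N": len(grp),
                "mean": grp["score"].mean(),
                "sd": grp["score"].std(ddof=1),
                "min": grp["score"].min(),
                "max": grp["score"].max(),
                "error_rate": float(wrong),
            }
        )
    return results, pd.DataFrame(rows).set_index("class")
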