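"""The seven base classifiers and their training/diagnostic machinery.

Model kinds (field-standard concretizations of the named families):

- ``NB``     Gaussian naive Bayes
- ``GLM``    L2-regularized logistic regression
- ``FLM``    fast large margin: linear hinge-loss SVM with Platt (sigmoid)
             calibration so its margin maps to a probability scale
- ``DL``     small feed-forward neural network
- ``DT``     CART decision tree
- ``RF``     random forest (500 trees)
- ``PLSDA``  partial least squares discriminant analysis, classifying by
             nearest class centroid in latent space

Every kind exposes the same prediction contract: a class label (EC or CTRL)
plus a confidence in [0, 1] that is 0 exactly at the decision boundary and
1 at certainty. Training is an exhaustive grid search over hyperparameters
scored by stratified k-fold cross-validated accuracy; the winning point is
refitted on all training data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.calibration import CalibratedClassifierCV
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import accuracy_score, roc_auc_score
from sklearn.model_selection import ParameterGrid, StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neural_network import MLPClassifier
from sklearn.svm import LinearSVC
from sklearn.tree import DecisionTreeClassifier

from .peaktable import CTRL, EC
from .preprocess import ProcessedMatrix

MODEL_KINDS = ("NB", "GLM", "FLM", "DL", "DT", "RF", "PLSDA")

#: Default hyperparameter grids, deliberately small: cohorts here are
#: hundreds of samples by ~250 autoscaled features.
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "NB": {"var_smoothing": [1e-9, 1e-8]},
    "GLM": {"C": [0.01, 0.1, 1.0, 10.0]},
    "FLM": {"C": [0.01, 0.1, 1.0]},
    "DL": {"hidden_layer_sizes": [(16,), (32, 16)], "alpha": [1e-4, 1e-2]},
    "DT": {"max_depth": [2, 4, 8], "min_samples_leaf": [1, 5]},
    "RF": {"max_features": ["sqrt", 0.3]},
    "PLSDA": {"n_components": [1, 2, 3]},
}


class PLSDAClassifier(BaseEstimator, ClassifierMixin):
    """PLS regression on the 0/1 class indicator, nearest-centroid decision.

    After fitting, samples are projected into latent space and assigned to
    the nearer class centroid. ``decision_function`` returns
    ``(d_ctrl - d_ec) / (d_ctrl + d_ec)`` in [-1, 1]: positive values favor
    the positive (EC) class, |value| is the centroid confidence, 1 when the
    sample coincides with a centroid.
    """

    def __init__(self, n_components: int = 1):
        self.n_components = n_components

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("PLSDA requires exactly two classes")
        max_rank = min(X.shape[0] - 1, X.shape[1])
        if self.n_components > max_rank:
            raise ValueError(
                f"n_components={self.n_components} exceeds data rank {max_rank}"
            )
        y01 = (y == self.classes_[1]).astype(float)
        self.pls_ = PLSRegression(n_components=self.n_components, scale=False)
        self.pls_.fit(X, y01)
        T = self.pls_.transform(X)
        self.centroid_neg_ = T[y01 == 0].mean(axis=0)
        self.centroid_pos_ = T[y01 == 1].mean(axis=0)
        return self

    def decision_function(self, X):
        T = self.pls_.transform(np.asarray(X, dtype=float))
        d_neg = np.linalg.norm(T - self.centroid_neg_, axis=1)
        d_pos = np.linalg.norm(T - self.centroid_pos_, axis=1)
        denom = d_neg + d_pos
        with np.errstate(invalid="ignore"):
            dec = np.where(denom > 0, (d_neg - d_pos) / denom, 0.0)
        return dec

    def predict(self, X):
        return np.where(self.decision_function(X) > 0, self.classes_[1], self.classes_[0])

    def predict_proba(self, X):
        p_pos = (1.0 + self.decision_function(X)) / 2.0
        return np.column_stack([1.0 - p_pos, p_pos])


def make_estimator(kind: str, seed: int = 0, **params):
    """Instantiate one model kind with optional hyperparameter overrides."""
    if kind == "NB":
        return GaussianNB(**params)
    if kind == "GLM":
        return LogisticRegression(max_iter=5000, **params)  # L2 by default
    if kind == "FLM":
        c = params.pop("C", 1.0)
        base = LinearSVC(C=c, loss="hinge", max_iter=20000, random_state=seed, **params)
        return CalibratedClassifierCV(base, method="sigmoid", cv=3)
    if kind == "DL":
        return MLPClassifier(
            solver="lbfgs", max_iter=2000, random_state=seed, **params
        )
    if kind == "DT":
        return DecisionTreeClassifier(random_state=seed, **params)
    if kind == "RF":
        n_estimators = params.pop("n_estimators", 500)
        return RandomForestClassifier(
            n_estimators=n_estimators, random_state=seed, **params
        )
    if kind == "PLSDA":
        return PLSDAClassifier(**params)
    raise ValueError(f"unknown model kind {kind!r}; expected one of {MODEL_KINDS}")


@dataclass
class TrainedModel:
    """One fitted base classifier plus its cross-validation scorecard."""

    kind: str
    features: list[str]
    estimator: object
    params: dict
    cv_accuracy: float
    cv_auc: float
    train_accuracy: float
    folds: int
    seed: int

    def __post_init__(self) -> None:
        if not self.features:
            raise ValueError("feature subset must be non-empty")
        for name in ("cv_accuracy", "cv_auc", "train_accuracy"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")

    @property
    def overfit_gap(self) -> float:
        return self.train_accuracy - self.cv_accuracy


def _cv_scores(estimator, X, y, folds, seed) -> tuple[float, float]:
    """Mean stratified k-fold accuracy and AUC for one grid point."""
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accs, aucs = [], []
    for train_idx, test_idx in cv.split(X, y):
        est = clone(estimator)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            est.fit(X[train_idx], y[train_idx])
        pred = est.predict(X[test_idx])
        accs.append(accuracy_score(y[test_idx], pred))
        proba = est.predict_proba(X[test_idx])[:, 1]
        if len(np.unique(y[test_idx])) == 2:
            aucs.append(roc_auc_score(y[test_idx], proba))
    return float(np.mean(accs)), float(np.mean(aucs)) if aucs else float("nan")


def train_model(
    kind: str,
    matrix: ProcessedMatrix,
    labels: pd.Series,
    grid: dict[str, list] | None = None,
    folds: int = 10,
    seed: int = 0,
) -> TrainedModel:
    """Grid-search one model kind by stratified k-fold CV accuracy.

    Every grid point is scored by mean CV accuracy (and AUC from its
    probability scores); the best point — first in grid order on ties, for
    determinism — is refitted on all training samples. Requires at least
    `folds` samples in each class.
    """
    if grid is None:
        grid = DEFAULT_GRIDS[kind]
    points = list(ParameterGrid(grid))
    if not points:
        raise ValueError("empty hyperparameter grid")
    y = (labels == EC).astype(int).to_numpy()
    counts = np.bincount(y, minlength=2)
    if counts.min() == 0:
        raise ValueError("both classes must be present in the training labels")
    if counts.min() < folds:
        raise ValueError(
            f"need at least folds={folds} samples per class, got {counts.min()}"
        )
    X = matrix.X.to_numpy()

    best = None
    for params in points:
        est = make_estimator(kind, seed=seed, **params)
        acc, auc = _cv_scores(est, X, y, folds, seed)
        if best is None or acc > best[0]:
            best = (acc, auc, params)

    acc, auc, params = best
    final = make_estimator(kind, seed=seed, **params)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        final.fit(X, y)
    train_acc = float(accuracy_score(y, final.predict(X)))
    return TrainedModel(
        kind=kind,
        features=list(matrix.features),
        estimator=final,
        params=params,
        cv_accuracy=acc,
        cv_auc=auc,
        train_accuracy=train_acc,
        folds=folds,
        seed=seed,
    )


def _confidences(model: TrainedModel, X: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized (labels, confidences) for a block of samples.

    Probabilistic kinds use ``confidence = 2 |p(EC) - 0.5|``; PLS-DA uses the
    relative centroid-distance margin (numerically the same quantity through
    its probability mapping). Exact ties at the boundary are labeled CTRL
    with confidence 0.
    """
    missing = [f for f in model.features if f not in X.columns]
    if missing:
        raise ValueError(f"sample(s) missing model features: {missing[:5]}")
    vals = X[model.features].to_numpy()
    if np.isnan(vals).any():
        raise ValueError("missing values in sample features")
    p_ec = model.estimator.predict_proba(vals)[:, 1]
    labels = np.where(p_ec > 0.5, EC, CTRL)
    conf = 2.0 * np.abs(p_ec - 0.5)
    return labels, conf


def predict_confidence(model: TrainedModel, sample: pd.Series) -> tuple[str, float]:
    """Classify one sample and return (label, confidence in [0, 1])."""
    X = sample.to_frame().T if isinstance(sample, pd.Series) else pd.DataFrame(
        [sample], columns=model.features
    )
    labels, conf = _confidences(model, X)
    return str(labels[0]), float(conf[0])


def admit_models(
    candidates: list[TrainedModel],
    min_accuracy: float = 0.65,
    min_auc: float = 0.85,
    max_overfit_gap: float = 0.15,
) -> list[TrainedModel]:
    """Keep models with CV accuracy > 65%, CV AUC > 0.85 and no overfitting.

    Inequalities are strict; "no overfitting" is operationalized as a
    training-minus-CV accuracy gap below `max_overfit_gap`. Order is
    preserved.
    """
    return [
        m
        for m in candidates
        if m.cv_accuracy > min_accuracy
        and m.cv_auc > min_auc
        and m.overfit_gap < max_overfit_gap
    ]


@dataclass
class PLSDADiagnostics:
    """PLS-DA model quality summary: VIP scores, R2/Q2, permutation test."""

    n_components: int
    vip: pd.Series
    r2: float
    q2: float
    permutation_p: float
    n_permutations: int

    def __post_init__(self) -> None:
        msq = float((self.vip**2).mean())
        if abs(msq - 1.0) > 1e-6:
            raise ValueError(f"mean squared VIP must be 1, got {msq}")
        if not 0 <= self.permutation_p <= 1:
            raise ValueError("permutation p must be in [0, 1]")


def _vip_scores(pls: PLSRegression, feature_names) -> pd.Series:
    """Variable importance in projection from weights, scores and y-loadings.

    VIP_j = sqrt( p * sum_a SSY_a (w_ja / ||w_a||)^2 / sum_a SSY_a ), where
    SSY_a is the class-indicator variance explained by component a. The
    normalization makes the mean squared VIP exactly 1.
    """
    W = pls.x_weights_
    T = pls.x_scores_
    q = pls.y_loadings_.ravel()
    p, a = W.shape
    ssy = (q**2) * np.einsum("ij,ij->j", T, T)
    wnorm2 = (W**2).sum(axis=0)
    contrib = (W**2 / wnorm2) @ ssy
    vip = np.sqrt(p * contrib / ssy.sum())
    return pd.Series(vip, index=feature_names, name="VIP")


def _q2(X: np.ndarray, y: np.ndarray, n_components: int, folds: int, seed: int) -> float:
    """Cross-validated fraction of class-indicator variance explained."""
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    press, tss = 0.0, float(((y - y.mean()) ** 2).sum())
    for train_idx, test_idx in cv.split(X, y):
        pls = PLSRegression(n_components=n_components, scale=False)
        pls.fit(X[train_idx], y[train_idx])
        yhat = pls.predict(X[test_idx]).ravel()
        press += float(((y[test_idx] - yhat) ** 2).sum())
    return 1.0 - press / tss


def plsda_diagnostics(
    matrix: ProcessedMatrix,
    labels: pd.Series,
    max_lv: int = 5,
    folds: int = 10,
    n_perm: int = 2000,
    seed: int = 0,
) -> PLSDADiagnostics:
    """Fit PLS-DA with CV-chosen latent-variable count and test it.

    The latent-variable count in 1..max_lv maximizing cross-validated
    classification accuracy is selected (smallest count on ties). VIP
    scores, in-sample R2 and cross-validated Q2 are computed for that
    model, and the permutation test refits the model on `n_perm`
    label-shuffled datasets: p = (1 + #{permuted Q2 >= observed Q2}) /
    (1 + n_perm).
    """
    X = matrix.X.to_numpy()
    y = (labels == EC).astype(int).to_numpy()
    max_rank = min(X.shape[0] - 1, X.shape[1])
    if max_lv > max_rank:
        raise ValueError(f"max_lv={max_lv} exceeds data rank {max_rank}")

    best_k, best_acc = 1, -np.inf
    for k in range(1, max_lv + 1):
        acc, _ = _cv_scores(PLSDAClassifier(n_components=k), X, y, folds, seed)
        if acc > best_acc:
            best_k, best_acc = k, acc

    pls = PLSRegression(n_components=best_k, scale=False)
    pls.fit(X, y.astype(float))
    yhat = pls.predict(X).ravel()
    r2 = 1.0 - float(((y - yhat) ** 2).sum()) / float(((y - y.mean()) ** 2).sum())
    q2 = _q2(X, y.astype(float), best_k, folds, seed)

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        y_perm = rng.permutation(y).astype(float)
        if len(np.unique(y_perm)) < 2:
            continue
        if _q2(X, y_perm, best_k, folds, seed) >= q2:
            exceed += 1
    p_value = (1 + exceed) / (1 + n_perm)

    return PLSDADiagnostics(
        n_components=best_k,
        vip=_vip_scores(pls, matrix.features),
        r2=r2,
        q2=q2,
        permutation_p=p_value,
        n_permutations=n_perm,
    )
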