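"""Pre-model feature screening and genetic-algorithm wrapper selection.

Screening drops features before any model sees them, on three criteria
applied in order (the first failing criterion tags the feature):

1. correlation — a feature whose point-biserial correlation with the class
   label is suspiciously high (|r| >= r_high, a leakage guard) or
   essentially zero (|r| <= r_low, uninformative) is excluded;
2. stability — a feature where more than `identical_frac` of the values are
   identical is near-constant and excluded;
3. missing — any feature still containing missing values is excluded.

The genetic algorithm then searches binary feature masks, scoring each mask
by the cross-validated accuracy of a given classifier restricted to the
masked features (a wrapper method), with tournament selection, uniform
crossover, bit-flip mutation and elitism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, cross_val_score

from .preprocess import ProcessedMatrix


@dataclass
class ScreenReport:
    """Outcome of the three screening criteria for every input feature."""

    retained: list[str]
    excluded: dict[str, str]  # feature -> reason tag

    REASONS = ("correlation_high", "correlation_null", "unstable", "missing")

    def reason_counts(self) -> dict[str, int]:
        counts = {r: 0 for r in self.REASONS}
        for reason in self.excluded.values():
            counts[reason] += 1
        return counts


@dataclass
class GAConfig:
    """Genetic-algorithm settings for wrapper feature selection.

    Fitness is the mean stratified k-fold cross-validated accuracy of the
    stated model kind on the masked features. Defaults are modest search
    settings suitable for a few hundred samples by ~250 features.
    """

    population_size: int = 50
    generations: int = 40
    crossover_rate: float = 0.8
    mutation_rate: float = 0.02
    elitism: int = 2
    cv_folds: int = 5
    tournament_size: int = 2
    init_density: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        for name in ("crossover_rate", "mutation_rate", "init_density"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.elitism < 0 or self.elitism >= self.population_size:
            raise ValueError("elitism must be in [0, population_size)")


def screen_features(
    matrix: ProcessedMatrix,
    labels: pd.Series,
    r_high: float = 0.95,
    r_low: float = 0.05,
    identical_frac: float = 0.80,
) -> ScreenReport:
    """Apply the correlation / stability / missing screening criteria.

    Labels must be binary. The point-biserial correlation (Pearson r
    against the 0/1 class indicator) is computed on non-missing values;
    features where it is undefined (constant features) fall through to the
    stability criterion. The stability boundary is exclusive: a feature
    with a most-common-value fraction strictly above `identical_frac`
    is excluded.
    """
    classes = pd.unique(labels)
    if len(classes) != 2:
        raise ValueError(f"labels must be binary, got classes {list(classes)}")
    y = (labels == sorted(map(str, classes))[-1]).astype(float)
    # also accepts a bare DataFrame, e.g. log values before autoscaling,
    # since screening may run while missing-containing features still exist
    data = matrix.X if hasattr(matrix, "X") else matrix

    retained: list[str] = []
    excluded: dict[str, str] = {}
    for feat in data.columns:
        col = data[feat]
        obs = col.dropna()
        r = np.nan
        if len(obs) > 1 and obs.nunique() > 1:
            r = float(np.corrcoef(obs.to_numpy(), y.loc[obs.index].to_numpy())[0, 1])
        if np.isfinite(r) and abs(r) >= r_high:
            excluded[feat] = "correlation_high"
            continue
        if np.isfinite(r) and abs(r) <= r_low:
            excluded[feat] = "correlation_null"
            continue
        if len(obs) and obs.value_counts(normalize=True).iloc[0] > identical_frac:
            excluded[feat] = "unstable"
            continue
        if col.isna().any():
            excluded[feat] = "missing"
            continue
        retained.append(feat)
    return ScreenReport(retained=retained, excluded=excluded)


def _mask_fitness(
    X: np.ndarray,
    y: np.ndarray,
    mask: np.ndarray,
    model_factory,
    cv_folds: int,
    seed: int,
) -> float:
    if not mask.any():
        return 0.0
    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    scores = cross_val_score(model_factory(), X[:, mask], y, cv=cv, scoring="accuracy")
    return float(scores.mean())


def ga_select(
    matrix: ProcessedMatrix,
    labels: pd.Series,
    model_kind: str,
    config: GAConfig,
) -> tuple[list[str], list[float]]:
    """Evolve a feature mask maximizing cross-validated accuracy.

    Returns the best feature subset found and the per-generation best
    fitness trace (non-decreasing whenever ``elitism >= 1``). Deterministic
    for a fixed ``config.seed``.
    """
    from .classifiers import make_estimator  # deferred: avoids import cycle

    features = list(matrix.features)
    if not features:
        raise ValueError("empty feature set after screening")
    X = matrix.X.to_numpy()
    y = (labels == "EC").astype(int).to_numpy()
    rng = np.random.default_rng(config.seed)
    p = len(features)

    def factory():
        return make_estimator(model_kind, seed=config.seed)

    def fitness(mask: np.ndarray) -> float:
        return _mask_fitness(X, y, mask, factory, config.cv_folds, config.seed)

    pop = rng.random((config.population_size, p)) < config.init_density
    # guarantee no empty chromosome at init
    for i in range(config.population_size):
        if not pop[i].any():
            pop[i, rng.integers(p)] = True
    fits = np.array([fitness(m) for m in pop])

    trace: list[float] = [float(fits.max())]
    for _ in range(config.generations):
        order = np.argsort(-fits, kind="stable")
        elite = pop[order[: config.elitism]].copy()

        children = []
        while len(children) < config.population_size - config.elitism:
            idx = rng.integers(0, config.population_size, size=config.tournament_size)
            a = idx[np.argmax(fits[idx])]
            idx = rng.integers(0, config.population_size, size=config.tournament_size)
            b = idx[np.argmax(fits[idx])]
            child = pop[a].copy()
            if rng.random() < config.crossover_rate:
                swap = rng.random(p) < 0.5
                child[swap] = pop[b][swap]
            flip = rng.random(p) < config.mutation_rate
            child[flip] = ~child[flip]
            if not child.any():
                child[rng.integers(p)] = True
            children.append(child)

        pop = np.vstack([elite, np.array(children)]) if config.elitism else np.array(children)
        fits = np.array([fitness(m) for m in pop])
        trace.append(float(fits.max()))

    best = pop[int(np.argmax(fits))]
    subset = [f for f, keep in zip(features, best) if keep]
    return subset, trace
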