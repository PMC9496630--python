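"""Peak-area preprocessing: internal-standard normalization, log, autoscale.

The fixed transform order is IS-normalize -> natural log -> autoscale
(per-feature mean-centering and division by the sample standard deviation).
Autoscale parameters are fitted on a designated training subset only and
frozen, so held-out samples are transformed with training-set statistics
and never leak information into validation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .peaktable import PeakTable


@dataclass
class ProcessedMatrix:
    """Autoscaled log feature matrix with the fitted transform parameters.

    `feature_means` / `feature_sds` are the per-feature mean and sample
    (n-1 denominator) standard deviation of the log IS-normalized values on
    the fitting subset; they are retained so the identical affine transform
    can be applied to new samples via :meth:`transform_new`.
    """

    X: pd.DataFrame
    labels: pd.Series
    feature_means: pd.Series
    feature_sds: pd.Series
    normalized: bool = True
    logged: bool = True
    autoscaled: bool = True

    @property
    def samples(self) -> pd.Index:
        return self.X.index

    @property
    def features(self) -> pd.Index:
        return self.X.columns

    def subset_samples(self, ids: Iterable) -> "ProcessedMatrix":
        ids = list(ids)
        return replace(self, X=self.X.loc[ids], labels=self.labels.loc[ids])

    def subset_features(self, names: Iterable[str]) -> "ProcessedMatrix":
        names = list(names)
        return replace(
            self,
            X=self.X[names],
            feature_means=self.feature_means[names],
            feature_sds=self.feature_sds[names],
        )

    def transform_new(self, table: PeakTable) -> "ProcessedMatrix":
        """Apply the frozen log/autoscale parameters to a new normalized table."""
        vals = table.areas[self.features.tolist()]
        if (vals <= 0).any().any():
            raise ValueError("all normalized values must be strictly positive")
        logged = np.log(vals)
        X = (logged - self.feature_means) / self.feature_sds
        return replace(self, X=X, labels=table.labels)

    def inverse_transform(self) -> pd.DataFrame:
        """Undo autoscale and log, recovering IS-normalized areas."""
        return np.exp(self.X * self.feature_sds + self.feature_means)

    # ------------------------------------------------------------------ I/O

    def to_csv(self, path: str | Path) -> None:
        """Matrix as CSV plus a JSON sidecar with parameters and flags."""
        path = Path(path)
        out = pd.concat([self.labels.rename("label"), self.X], axis=1)
        out.to_csv(path, index_label="sample_id")
        sidecar = {
            "feature_means": self.feature_means.to_dict(),
            "feature_sds": self.feature_sds.to_dict(),
            "flags": {
                "normalized": self.normalized,
                "logged": self.logged,
                "autoscaled": self.autoscaled,
            },
        }
        path.with_suffix(".params.json").write_text(json.dumps(sidecar, indent=1))


def normalize_to_is(table: PeakTable) -> PeakTable:
    """Divide every peak area by its sample's internal-standard area.

    Missing peaks stay missing. Raises if any sample has a nonpositive
    internal-standard area, naming the sample.
    """
    bad = table.is_area[~(table.is_area > 0)]
    if len(bad):
        raise ValueError(
            f"nonpositive internal-standard area for sample(s) {bad.index.tolist()}"
        )
    areas = table.areas.div(table.is_area, axis=0)
    ones = pd.Series(1.0, index=table.samples, name="is_area")
    return replace(table, areas=areas, is_area=ones, normalized=True)


def impute_missing(
    table: PeakTable, strategy: Literal["half_min", "feature_median"] = "half_min"
) -> tuple[PeakTable, int]:
    """Fill sporadic missing cells in a normalized table.

    ``half_min`` imputes half the feature's minimum observed value (a
    detection-limit surrogate); ``feature_median`` imputes the feature
    median. Returns the completed table and the number of imputed cells.
    """
    if strategy not in ("half_min", "feature_median"):
        raise ValueError(f"unknown imputation strategy {strategy!r}")
    n_missing = int(table.areas.isna().sum().sum())
    if n_missing == 0:
        return table, 0
    if strategy == "half_min":
        fill = table.areas.min(axis=0, skipna=True) / 2.0
    else:
        fill = table.areas.median(axis=0, skipna=True)
    areas = table.areas.fillna(fill)
    return replace(table, areas=areas), n_missing


def log_and_autoscale(
    table: PeakTable, fit_on: Iterable | None = None
) -> ProcessedMatrix:
    """Natural log then autoscale, with parameters fitted on `fit_on` only.

    Parameters
    ----------
    table : PeakTable
        IS-normalized, complete (imputed) table with strictly positive values.
    fit_on : iterable of sample ids, optional
        Subset on which per-feature means and standard deviations are
        computed (the training set). All samples in `table` are transformed
        with those parameters. Defaults to all samples.

    Features that are constant on the fitting subset (sd = 0) are dropped
    with a warning, since autoscaling them is undefined.
    """
    fit_ids = list(fit_on) if fit_on is not None else list(table.samples)
    if not fit_ids:
        raise ValueError("empty fitting subset")
    vals = table.areas
    if vals.isna().any().any():
        raise ValueError("missing values present; impute before log_and_autoscale")
    if (vals <= 0).any().any():
        raise ValueError("all normalized values must be strictly positive")

    logged = np.log(vals)
    means = logged.loc[fit_ids].mean(axis=0)
    sds = logged.loc[fit_ids].std(axis=0, ddof=1)

    # sd == 0 up to float noise counts as constant
    tol = 1e-12 * np.maximum(1.0, means.abs())
    constant = sds[sds <= tol].index.tolist()
    if constant:
        warnings.warn(
            f"dropping {len(constant)} constant feature(s) on the fitting "
            f"subset: {constant[:5]}",
            stacklevel=2,
        )
        logged = logged.drop(columns=constant)
        means = means.drop(constant)
        sds = sds.drop(constant)

    X = (logged - means) / sds
    return ProcessedMatrix(
        X=X, labels=table.labels.copy(), feature_means=means, feature_sds=sds
    )
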