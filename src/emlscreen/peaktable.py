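"""Sample x metabolite peak-area tables.

The entry format for the whole pipeline: one row per serum sample, one
column per metabolite feature (GC-MS peak area), plus the internal-standard
peak area and a class label per sample. Missing peaks are NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

#: Canonical class labels. EC is always the positive class.
CTRL = "CTRL"
EC = "EC"


@dataclass
class PeakTable:
    """Raw or internal-standard-normalized peak areas with sample metadata.

    Attributes
    ----------
    areas : pandas.DataFrame
        Samples in rows, features in columns. Non-negative peak areas;
        NaN marks a missing (undetected) peak.
    labels : pandas.Series
        One class label per sample (``"CTRL"``, ``"EC"``, or another
        disease-class tag), indexed like ``areas``.
    is_area : pandas.Series
        Internal-standard peak area per sample; strictly positive.
    batch : pandas.Series or None
        Optional analytical batch id per sample.
    normalized : bool
        True once areas have been divided by the internal standard.
    """

    areas: pd.DataFrame
    labels: pd.Series
    is_area: pd.Series
    batch: pd.Series | None = None
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.areas.columns.duplicated().any():
            dup = self.areas.columns[self.areas.columns.duplicated()].tolist()
            raise ValueError(f"duplicate feature names: {dup}")
        if not self.areas.index.equals(self.labels.index):
            raise ValueError("labels index does not match areas index")
        if not self.areas.index.equals(self.is_area.index):
            raise ValueError("is_area index does not match areas index")
        bad = self.is_area[~(self.is_area > 0)]
        if len(bad):
            raise ValueError(
                "internal-standard area must be strictly positive; offending "
                f"samples: {bad.index.tolist()[:5]}"
            )

    @property
    def samples(self) -> pd.Index:
        return self.areas.index

    @property
    def features(self) -> pd.Index:
        return self.areas.columns

    @property
    def n_samples(self) -> int:
        return len(self.areas)

    @property
    def n_features(self) -> int:
        return self.areas.shape[1]

    def subset_samples(self, ids: Iterable) -> "PeakTable":
        ids = list(ids)
        return replace(
            self,
            areas=self.areas.loc[ids],
            labels=self.labels.loc[ids],
            is_area=self.is_area.loc[ids],
            batch=None if self.batch is None else self.batch.loc[ids],
        )

    def subset_features(self, names: Iterable[str]) -> "PeakTable":
        names = list(names)
        return replace(self, areas=self.areas[names])

    def binary_labels(self, positive: str = EC) -> pd.Series:
        """0/1 encoding with `positive` (default EC) mapped to 1."""
        return (self.labels == positive).astype(int)

    # ------------------------------------------------------------------ I/O

    def to_csv(self, path: str | Path, sep: str = ",") -> None:
        """Write as a flat table: sample id, label, is_area, then features."""
        out = pd.concat(
            [self.labels.rename("label"), self.is_area.rename("is_area"), self.areas],
            axis=1,
        )
        if self.batch is not None:
            out.insert(2, "batch", self.batch)
        out.to_csv(path, sep=sep, index_label="sample_id")

    @classmethod
    def from_csv(cls, path: str | Path, sep: str = ",") -> "PeakTable":
        df = pd.read_csv(path, sep=sep, index_col="sample_id")
        if "label" not in df.columns or "is_area" not in df.columns:
            raise ValueError("peak table file needs 'label' and 'is_area' columns")
        labels = df.pop("label").astype(str)
        is_area = df.pop("is_area").astype(float)
        batch = df.pop("batch") if "batch" in df.columns else None
        return cls(areas=df.astype(float), labels=labels, is_area=is_area, batch=batch)
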