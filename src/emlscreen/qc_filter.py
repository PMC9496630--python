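"""Analytical batch quality control and feature-presence filtering.

Each GC-MS batch of up to 25 study samples carries four control injections:
a solvent blank, a standard mix of 15 reference molecules, a pooled serum
sample, and a duplicate injection of one in-batch sample. A batch is
accepted only if all four controls pass:

1. the blank generates no peaks;
2. every standard-mix analyte's internal-standard-normalized area is within
   10% of its expected value;
3. over the 100 highest peaks of the duplicated sample, the normalized-area
   deviation of the repeat from the first injection is below 15%;
4. the pooled injection lands where the other pooled injections land —
   its distance from the pooled centroid is below 5% of the data's total
   standard-deviation norm.

Features that are not detected in at least 80% of samples are dropped
before any statistics are computed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .peaktable import PeakTable

DUPLICATE_TOP_N = 100


@dataclass
class BatchRecord:
    """One analytical batch: member samples plus its four QC injections.

    All profiles are raw peak areas over the same feature set as `samples`;
    each injection has its own internal-standard area. The standard mix is
    a separate small panel of reference molecules with known expected
    IS-normalized areas.
    """

    batch_id: str
    samples: pd.DataFrame          # member samples x features, raw areas
    sample_is: pd.Series           # member internal-standard areas
    blank: pd.Series               # raw areas; all zero when clean
    standard_measured: pd.Series   # raw areas of the reference molecules
    standard_expected: pd.Series   # expected IS-normalized areas
    standard_is: float
    pooled: pd.Series              # raw areas of the pooled injection
    pooled_is: float
    duplicate_of: str              # sample id of the re-injected sample
    duplicate: pd.Series           # raw areas of the repeat injection
    duplicate_is: float

    def __post_init__(self) -> None:
        if self.duplicate_of not in self.samples.index:
            raise ValueError(
                f"duplicate source {self.duplicate_of!r} is not a member of "
                f"batch {self.batch_id!r}"
            )

    @property
    def pooled_normalized(self) -> pd.Series:
        return self.pooled / self.pooled_is


@dataclass
class QCReport:
    """Per-condition outcome for one batch."""

    batch_id: str
    blank_pass: bool
    blank_peak_count: int
    standard_pass: bool
    standard_max_deviation: float
    duplicate_pass: bool
    duplicate_mean_deviation: float
    duplicate_max_deviation: float
    pooled_pass: bool
    pooled_deviation: float

    @property
    def overall_pass(self) -> bool:
        return (
            self.blank_pass
            and self.standard_pass
            and self.duplicate_pass
            and self.pooled_pass
        )

    def as_dict(self) -> dict:
        d = {
            "batch_id": self.batch_id,
            "blank": {"pass": self.blank_pass, "peak_count": self.blank_peak_count},
            "standard_mix": {
                "pass": self.standard_pass,
                "max_relative_deviation": self.standard_max_deviation,
            },
            "duplicate": {
                "pass": self.duplicate_pass,
                "mean_relative_deviation": self.duplicate_mean_deviation,
                "max_relative_deviation": self.duplicate_max_deviation,
            },
            "pooled": {"pass": self.pooled_pass, "deviation": self.pooled_deviation},
            "overall_pass": self.overall_pass,
        }
        return d


def validate_batch(
    batch: BatchRecord,
    tol_standard: float = 0.10,
    tol_duplicate: float = 0.15,
    tol_pooled: float = 0.05,
    pooled_reference: pd.Series | None = None,
    detection_floor: float = 0.0,
) -> QCReport:
    """Check the four batch-acceptance conditions.

    Parameters
    ----------
    batch : BatchRecord
    tol_standard : float
        Maximum allowed relative deviation of any standard-mix analyte's
        IS-normalized area from its expected value (default 10%).
    tol_duplicate : float
        Maximum allowed mean relative deviation, over the duplicated
        sample's 100 highest peaks, of the repeat injection from the first
        (default 15%). The per-peak maximum is also reported.
    tol_pooled : float
        Maximum allowed pooled-injection deviation score: Euclidean
        distance of the IS-normalized pooled profile from the pooled
        centroid, divided by the norm of the per-feature standard
        deviations of the batch members (default 5% of total spread).
    pooled_reference : pandas.Series, optional
        IS-normalized centroid of pooled injections from previously
        accepted batches. When absent (the first batch), condition 4
        passes with deviation 0 by convention.
    detection_floor : float
        Areas at or below this value count as "no peak" in the blank.

    Returns
    -------
    QCReport
    """
    for name in ("blank", "standard_measured", "pooled", "duplicate"):
        if getattr(batch, name) is None:
            raise ValueError(f"batch {batch.batch_id!r} is missing its {name} profile")

    # condition 1: solvent blank generates no peaks
    blank_peaks = int((batch.blank.to_numpy() > detection_floor).sum())
    blank_pass = blank_peaks == 0

    # condition 2: standard-mix analytes within tol of expected normalized area
    measured_norm = batch.standard_measured / batch.standard_is
    expected = batch.standard_expected.reindex(measured_norm.index)
    std_dev = float(np.max(np.abs(measured_norm / expected - 1.0)))
    standard_pass = std_dev <= tol_standard

    # condition 3: duplicate injection, top-100 peaks of the first injection
    original = batch.samples.loc[batch.duplicate_of] / batch.sample_is[batch.duplicate_of]
    repeat = batch.duplicate / batch.duplicate_is
    top = original.dropna().nlargest(min(DUPLICATE_TOP_N, original.notna().sum())).index
    rel = np.abs(repeat[top] - original[top]) / original[top]
    rel = rel.dropna()
    dup_mean = float(rel.mean())
    dup_max = float(rel.max())
    duplicate_pass = dup_mean < tol_duplicate

    # condition 4: pooled injection close to the pooled centroid,
    # relative to the total spread of the batch members
    if pooled_reference is None:
        pooled_dev = 0.0
        pooled_pass = True
    else:
        member_norm = batch.samples.div(batch.sample_is, axis=0)
        sd_norm = float(np.linalg.norm(member_norm.std(ddof=1).fillna(0.0)))
        diff = (batch.pooled_normalized - pooled_reference).fillna(0.0)
        pooled_dev = float(np.linalg.norm(diff) / sd_norm) if sd_norm > 0 else np.inf
        pooled_pass = pooled_dev < tol_pooled

    return QCReport(
        batch_id=batch.batch_id,
        blank_pass=blank_pass,
        blank_peak_count=blank_peaks,
        standard_pass=standard_pass,
        standard_max_deviation=std_dev,
        duplicate_pass=duplicate_pass,
        duplicate_mean_deviation=dup_mean,
        duplicate_max_deviation=dup_max,
        pooled_pass=pooled_pass,
        pooled_deviation=pooled_dev,
    )


def validate_batches(batches: list[BatchRecord], **kwargs) -> list[QCReport]:
    """Validate batches in acquisition order with a running pooled centroid.

    The first batch's pooled injection seeds the centroid; each subsequent
    batch is compared against the mean of the pooled profiles seen so far.
    """
    reports: list[QCReport] = []
    pooled_seen: list[pd.Series] = []
    for batch in batches:
        ref = None
        if pooled_seen:
            ref = pd.concat(pooled_seen, axis=1).mean(axis=1)
        reports.append(validate_batch(batch, pooled_reference=ref, **kwargs))
        pooled_seen.append(batch.pooled_normalized)
    return reports


def filter_features(
    table: PeakTable, presence_threshold: float = 0.80
) -> tuple[PeakTable, list[str]]:
    """Keep features detected in at least `presence_threshold` of samples.

    Returns the filtered table and the removed feature names sorted
    alphabetically. The sample set is unchanged. The boundary is
    inclusive: presence exactly at the threshold is retained.
    """
    if not 0 < presence_threshold <= 1:
        raise ValueError(f"presence_threshold must be in (0, 1], got {presence_threshold}")
    if table.n_samples == 0:
        raise ValueError("empty peak table")
    presence = table.areas.notna().mean(axis=0)
    keep = presence[presence >= presence_threshold].index
    removed = sorted(set(table.features) - set(keep))
    return table.subset_features([f for f in table.features if f in set(keep)]), removed
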