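"""Synthetic serum GC-MS cohorts with planted metabolite effects.

Real untargeted serum metabolomes for case-control endometrial-cancer (EC)
work are not publicly depositable, so this module generates peak tables with
the statistical structure the analysis assumes: log-normal raw peak areas,
an internal-standard column, a configurable set of effect metabolites whose
EC-group abundance differs from controls by a true fold change on the raw
scale, completely-at-random missingness, and 25-sample analytical batches
carrying the four QC injections (blank, standard mix, pooled, duplicate).

Every downstream stage of the pipeline is testable against these tables
because the planted truth is known.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .peaktable import CTRL, EC, PeakTable
from .qc_filter import BatchRecord


class Effect(NamedTuple):
    """One planted metabolite effect: raw-scale EC/CTRL fold change."""

    name: str
    fold_change: float

    @property
    def direction(self) -> str:
        return "up" if self.fold_change > 1.0 else "down"


#: Default planted effect set: the 12 volcano metabolites. Glycerol,
#: 3-hydroxybutyric acid and stearic acid are raised in EC serum; the other
#: nine are lowered. Magnitudes (3x up, 3x down) are configurable defaults,
#: not measured values.
DEFAULT_EFFECTS: tuple[Effect, ...] = (
    Effect("glycerol", 3.0),
    Effect("3-hydroxybutyric acid", 3.0),
    Effect("stearic acid", 3.0),
    Effect("glycine", 1 / 3),
    Effect("phenyl pyruvic acid", 1 / 3),
    Effect("serine", 1 / 3),
    Effect("valine", 1 / 3),
    Effect("urea", 1 / 3),
    Effect("oxyproline", 1 / 3),
    Effect("phenylalanine", 1 / 3),
    Effect("glyceraldehyde 3-phosphate", 1 / 3),
    Effect("gluconic acid", 1 / 3),
)

#: The 15-molecule standard mix injected with every batch (organic acids,
#: sugars, amino acids, steroids, fatty acids) with its expected
#: internal-standard-normalized peak areas.
STANDARD_MIX_EXPECTED: dict[str, float] = {
    "lactic acid": 0.80,
    "succinic acid": 0.45,
    "citric acid": 0.60,
    "malic acid": 0.35,
    "glucose": 1.50,
    "fructose": 0.90,
    "sucrose": 0.40,
    "alanine": 0.70,
    "leucine": 0.55,
    "methionine": 0.25,
    "cholesterol": 1.10,
    "stigmasterol": 0.30,
    "palmitic acid": 1.20,
    "oleic acid": 0.95,
    "myristic acid": 0.50,
}


@dataclass
class CohortConfig:
    """Parameters of a synthetic case-control cohort.

    Attributes
    ----------
    n_ctrl, n_ec : int
        Samples per arm.
    n_features : int
        Total metabolite features (default 251, the size of a typical
        retained untargeted serum panel after the 80%-presence filter).
    effect_features : sequence of Effect
        Planted (metabolite, raw-scale fold change) pairs; the EC geometric
        mean equals the CTRL geometric mean times the fold change in
        expectation. Defaults to the 12 volcano metabolites.
    base_log_mean, base_log_sd : float
        Location and typical scale of per-feature natural-log peak areas.
    missing_rate : float
        Probability that any single peak is missing (completely at random).
    is_area : float
        Nominal internal-standard peak area (2-isopropyl malic acid spike);
        per-sample areas vary by ~5% around it.
    seed : int
        Generator seed; fixed seed gives bit-identical tables.
    """

    n_ctrl: int = 100
    n_ec: int = 100
    n_features: int = 251
    effect_features: Sequence[Effect] = DEFAULT_EFFECTS
    base_log_mean: float = 11.0
    base_log_sd: float = 0.5
    missing_rate: float = 0.02
    is_area: float = 1.0e6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ctrl <= 0 or self.n_ec <= 0 or self.n_features <= 0:
            raise ValueError("sample and feature counts must be positive")
        if not 0 <= self.missing_rate <= 1:
            raise ValueError(f"missing_rate must be in [0, 1], got {self.missing_rate}")
        if self.is_area <= 0:
            raise ValueError("internal-standard area must be positive")
        self.effect_features = tuple(
            e if isinstance(e, Effect) else Effect(*e[:2]) for e in self.effect_features
        )
        if any(e.fold_change <= 0 for e in self.effect_features):
            raise ValueError("every effect fold change must be > 0")
        if self.n_features < len(self.effect_features):
            raise ValueError(
                f"n_features={self.n_features} is smaller than the "
                f"{len(self.effect_features)} effect features"
            )


def _feature_names(config: CohortConfig) -> list[str]:
    names = [e.name for e in config.effect_features]
    width = max(4, len(str(config.n_features)))
    k = len(names)
    names += [f"met_{i + 1:0{width}d}" for i in range(k, config.n_features)]
    return names


def generate_cohort(config: CohortConfig) -> PeakTable:
    """Draw a synthetic peak table with the configured planted effects.

    Raw areas are log-normal: each feature gets its own log-mean and
    log-sd (sampled once per cohort), and each effect feature's EC samples
    are shifted by ``log(fold_change)`` so the fold change holds on the
    geometric-mean (and hence the volcano) scale. Missing cells are
    inserted completely at random; the internal standard is never missing.
    """
    rng = np.random.default_rng(config.seed)
    names = _feature_names(config)
    n = config.n_ctrl + config.n_ec

    log_mu = rng.normal(config.base_log_mean, 1.0, size=config.n_features)
    log_sd = config.base_log_sd * rng.uniform(0.5, 1.5, size=config.n_features)

    z = rng.standard_normal((n, config.n_features))
    log_areas = log_mu + z * log_sd

    labels = np.array([CTRL] * config.n_ctrl + [EC] * config.n_ec)
    ec_mask = labels == EC
    for j, eff in enumerate(config.effect_features):
        log_areas[ec_mask, j] += np.log(eff.fold_change)

    areas = np.exp(log_areas)
    if config.missing_rate > 0:
        areas[rng.random(areas.shape) < config.missing_rate] = np.nan

    ids = [f"CTRL_{i + 1:03d}" for i in range(config.n_ctrl)] + [
        f"EC_{i + 1:03d}" for i in range(config.n_ec)
    ]
    is_area = config.is_area * np.exp(rng.normal(0.0, 0.05, size=n))

    index = pd.Index(ids, name="sample_id")
    return PeakTable(
        areas=pd.DataFrame(areas, index=index, columns=names),
        labels=pd.Series(labels, index=index, name="label"),
        is_area=pd.Series(is_area, index=index, name="is_area"),
    )


def generate_batches(
    table: PeakTable,
    batch_size: int = 25,
    seed: int = 0,
    qc_noise: float = 0.005,
    n_pooled: int = 50,
) -> list[BatchRecord]:
    """Split a cohort into acquisition batches with four QC injections each.

    The pooled profile is built once from `n_pooled` randomly selected
    samples (all samples when fewer are available), mimicking a pooled
    serum mixture injected with every batch; each injection perturbs it by
    `qc_noise` multiplicative log-normal noise. The duplicate injection
    repeats one randomly chosen in-batch sample with the same noise level.
    """
    if table.n_samples == 0:
        raise ValueError("empty peak table")
    rng = np.random.default_rng(seed)

    norm = table.areas.div(table.is_area, axis=0)
    chosen = rng.choice(
        table.samples, size=min(n_pooled, table.n_samples), replace=False
    )
    pooled_base = norm.loc[chosen].mean(axis=0, skipna=True)

    batches: list[BatchRecord] = []
    ids = list(table.samples)
    for b, start in enumerate(range(0, len(ids), batch_size)):
        member_ids = ids[start : start + batch_size]
        members = table.areas.loc[member_ids]
        member_is = table.is_area.loc[member_ids]

        std_is = float(table.is_area.median())
        expected = pd.Series(STANDARD_MIX_EXPECTED, name="expected")
        measured = expected * std_is * np.exp(
            rng.normal(0.0, qc_noise, size=len(expected))
        )

        pooled = pooled_base * np.exp(
            rng.normal(0.0, qc_noise, size=len(pooled_base))
        )

        dup_id = str(rng.choice(member_ids))
        dup_is = float(member_is[dup_id])
        duplicate = members.loc[dup_id] * np.exp(
            rng.normal(0.0, qc_noise, size=table.n_features)
        )

        batches.append(
            BatchRecord(
                batch_id=f"batch_{b + 1:02d}",
                samples=members,
                sample_is=member_is,
                blank=pd.Series(0.0, index=table.features),
                standard_measured=measured.rename("measured"),
                standard_expected=expected,
                standard_is=std_is,
                pooled=pooled,
                pooled_is=1.0,
                duplicate_of=dup_id,
                duplicate=duplicate,
                duplicate_is=dup_is,
            )
        )
    return batches


FailureMode = Literal["blank_peak", "standard_drift", "duplicate_variance", "pooled_outlier"]


def corrupt_batch(
    batch: BatchRecord, failure_mode: FailureMode, magnitude: float, seed: int = 0
) -> BatchRecord:
    """Inject a QC failure of the given relative magnitude into one control.

    The corruption targets exactly one acceptance condition:

    - ``blank_peak``: plants a peak of area ``magnitude`` x the
      internal-standard area in the blank (any positive magnitude fails
      condition 1).
    - ``standard_drift``: sets one standard-mix analyte to exactly
      ``(1 + magnitude)`` times its expected normalized area.
    - ``duplicate_variance``: regenerates the duplicate as the original
      sample scaled by exactly ``(1 + magnitude)`` per peak, so the mean
      relative deviation equals ``magnitude``.
    - ``pooled_outlier``: displaces the pooled profile by ``magnitude``
      times the member-sample per-feature standard deviations, so the
      pooled deviation score is ``magnitude`` up to the batch's own small
      pooled scatter.
    """
    if magnitude <= 0:
        raise ValueError("magnitude must be > 0")
    rng = np.random.default_rng(seed)

    if failure_mode == "blank_peak":
        blank = batch.blank.copy()
        feat = rng.choice(blank.index)
        blank[feat] = magnitude * float(batch.sample_is.median())
        return replace(batch, blank=blank)

    if failure_mode == "standard_drift":
        measured = batch.standard_measured.copy()
        analyte = rng.choice(measured.index)
        measured[analyte] = (
            batch.standard_expected[analyte] * batch.standard_is * (1.0 + magnitude)
        )
        return replace(batch, standard_measured=measured)

    if failure_mode == "duplicate_variance":
        original = batch.samples.loc[batch.duplicate_of]
        duplicate = original * (batch.duplicate_is / batch.sample_is[batch.duplicate_of])
        duplicate = duplicate * (1.0 + magnitude)
        return replace(batch, duplicate=duplicate)

    if failure_mode == "pooled_outlier":
        member_norm = batch.samples.div(batch.sample_is, axis=0)
        sd = member_norm.std(ddof=1).fillna(0.0)
        pooled = batch.pooled + magnitude * sd * batch.pooled_is
        return replace(batch, pooled=pooled)

    raise ValueError(f"unknown failure_mode {failure_mode!r}")
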