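import numpy as np
import pandas as pd
import pytest

from emlscreen import CohortConfig, PeakTable, generate_cohort
from emlscreen.peaktable import CTRL, EC


@pytest.fixture(scope="session")
def small_cohort() -> PeakTable:
    """Complete (no missing) 40+40 cohort with the default planted effects."""
    cfg = CohortConfig(n_ctrl=40, n_ec=40, n_features=60, missing_rate=0.0, seed=101)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def null_cohort() -> PeakTable:
    """Cohort with no planted effects: labels independent of features."""
    cfg = CohortConfig(
        n_ctrl=40, n_ec=40, n_features=40, effect_features=(), missing_rate=0.0, seed=77
    )
    return generate_cohort(cfg)


def make_table(areas: np.ndarray, labels, is_area=None, features=None) -> PeakTable:
    """Hand-build a PeakTable from a raw array."""
    n, p = np.asarray(areas).shape
    idx = pd.Index([f"s{i}" for i in range(n)], name="sample_id")
    cols = features if features is not None else [f"f{j}" for j in range(p)]
    if is_area is None:
        is_area = np.ones(n)
    return PeakTable(
        areas=pd.DataFrame(np.asarray(areas, dtype=float), index=idx, columns=cols),
        labels=pd.Series(list(labels), index=idx, name="label"),
        is_area=pd.Series(np.asarray(is_area, dtype=float), index=idx, name="is_area"),
    )


@pytest.fixture
def separable_table() -> PeakTable:
    """Two well-separated Gaussian clouds: trivially classifiable."""
    rng = np.random.default_rng(5)
    n = 40
    x_ctrl = rng.normal(0.0, 0.3, size=(n, 5))
    x_ec = rng.normal(4.0, 0.3, size=(n, 5))
    areas = np.exp(np.vstack([x_ctrl, x_ec]))  # positive raw scale
    return make_table(areas, [CTRL] * n + [EC] * n)
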