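import numpy as np
import pandas as pd
import pytest

from polyexposure.cohort import CohortTable
from polyexposure.simulate import TruthSpec, generate_cohort


def make_cohort(frame: pd.DataFrame, family: str = "lm",
                roles=None, kinds=None, levels=None) -> CohortTable:
    """Wrap a raw DataFrame (ID/PHENO[/TIME] + columns) into a validated
    CohortTable, inferring roles (exposure) and kinds when not given."""
    cols = [c for c in frame.columns if c not in ("ID", "PHENO", "TIME")]
    roles = roles or {c: "exposure" for c in cols}
    kinds = kinds or {c: ("continuous" if pd.api.types.is_numeric_dtype(frame[c])
                          else "categorical") for c in cols}
    return CohortTable(frame.reset_index(drop=True), family, roles, kinds,
                       levels or {}).validate()


@pytest.fixture
def lm_synthetic():
    """Small continuous-outcome cohort with 4 true of 8 exposures."""
    spec = TruthSpec(n=800, n_continuous=8, n_categorical=0, seed=42,
                     effects={"exp01": 0.4, "exp02": 0.4, "exp03": 0.4,
                              "exp04": 0.4},
                     missing_rate=0.02, unwanted_rate=0.0)
    return generate_cohort(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
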