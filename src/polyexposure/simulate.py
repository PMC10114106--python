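"""Seeded synthetic cohorts with known ground truth.

The generator emulates the structure of biobank-style exposome data: a
block of mixed continuous/categorical exposures sharing an exchangeable
latent-Gaussian correlation, forced-in covariates (age, sex), a sparse true
model on the latent (standardized) scale with optional pairwise
interactions, three outcome families (continuous, binary, censored
survival from an exponential hazard with uniform censoring), plus
missingness and categorical "unwanted" survey codes injected at stated
rates. Every draw is reproducible from the spec's seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .cohort import CohortTable

UNWANTED_CODE = "prefer_not_to_answer"


@dataclass
class TruthSpec:
    """Generating model of one synthetic cohort.

    Effects are on the standardized latent scale (each exposure's latent is
    a standard normal), so an ``effects`` entry of 0.3 means a 0.3-SD shift
    of the linear predictor per SD of that exposure. Categorical exposures
    act through their latent variable, giving monotone level effects.
    """

    n: int = 2000
    n_continuous: int = 16
    n_categorical: int = 4
    categorical_levels: int = 3
    rho: float = 0.2
    effects: dict = field(default_factory=lambda: {
        "exp01": 0.3, "exp02": 0.3, "exp03": 0.3, "exp04": 0.3})
    interaction_effects: dict = field(default_factory=dict)
    covariate_effects: dict = field(default_factory=lambda: {"age": 0.1, "sex": 0.2})
    family: str = "lm"
    intercept: float = 0.0
    noise_sd: float = 1.0
    baseline_hazard: float = 0.05
    censor_horizon: float = 10.0
    missing_rate: float = 0.02
    unwanted_rate: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must lie in [0, 1)")
        for r in (self.missing_rate, self.unwanted_rate):
            if not 0.0 <= r < 1.0:
                raise ValueError("rates must lie in [0, 1)")
        names = set(self.exposure_names())
        unknown = (set(self.effects) | {e for p in self.interaction_effects for e in p}) - names
        if unknown:
            raise ValueError(f"effects refer to unknown exposures: {sorted(unknown)}")
        # hierarchy: both parents of a declared interaction carry a declared
        # (possibly zero) main-effect entry
        for a, b in self.interaction_effects:
            self.effects.setdefault(a, 0.0)
            self.effects.setdefault(b, 0.0)

    def exposure_names(self) -> list[str]:
        cont = [f"exp{j + 1:02d}" for j in range(self.n_continuous)]
        cat = [f"cat{j + 1:02d}" for j in range(self.n_categorical)]
        return cont + cat

    def to_yaml(self) -> str:
        doc = dataclasses.asdict(self)
        doc["interaction_effects"] = {" * ".join(k): v
                                      for k, v in self.interaction_effects.items()}
        return yaml.safe_dump(doc, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "TruthSpec":
        doc = yaml.safe_load(text)
        doc["interaction_effects"] = {tuple(k.split(" * ")): v
                                      for k, v in doc.get("interaction_effects", {}).items()}
        return cls(**doc)


@dataclass
class SyntheticCohort:
    cohort: CohortTable
    truth: TruthSpec
    unwanted: dict[str, set]
    latent: pd.DataFrame            # the pre-missingness latent exposures
    linear_predictor: np.ndarray    # true eta per individual


def _quantile_levels(z: np.ndarray, n_levels: int) -> np.ndarray:
    from scipy.stats import norm
    cuts = norm.ppf(np.linspace(0, 1, n_levels + 1)[1:-1])
    idx = np.searchsorted(cuts, z)
    return np.array([f"level{j + 1}" for j in idx])


def generate_cohort(spec: TruthSpec) -> SyntheticCohort:
    """Draw one cohort from the generating model.

    Missingness and unwanted-code injection touch only exposure columns,
    never ID/PHENO/TIME or the covariates.
    """
    rng = np.random.default_rng(spec.seed)
    names = spec.exposure_names()
    p = len(names)
    common = rng.standard_normal(spec.n)
    eps = rng.standard_normal((spec.n, p))
    Z = np.sqrt(spec.rho) * common[:, None] + np.sqrt(1.0 - spec.rho) * eps
    latent = pd.DataFrame(Z, columns=names)

    age = rng.normal(57.0, 8.0, spec.n)
    sex = rng.integers(0, 2, spec.n).astype(float)
    eta = np.full(spec.n, float(spec.intercept))
    for name, b in spec.effects.items():
        eta += b * latent[name].to_numpy()
    for (a, b_), coef in spec.interaction_effects.items():
        eta += coef * latent[a].to_numpy() * latent[b_].to_numpy()
    eta += spec.covariate_effects.get("age", 0.0) * (age - 57.0) / 8.0
    eta += spec.covariate_effects.get("sex", 0.0) * sex

    frame = pd.DataFrame({"ID": [f"S{i + 1:06d}" for i in range(spec.n)]})
    if spec.family == "lm":
        frame["PHENO"] = eta + rng.normal(0.0, spec.noise_sd, spec.n)
    elif spec.family == "logistic":
        from scipy.special import expit
        frame["PHENO"] = rng.binomial(1, expit(eta)).astype(int)
    elif spec.family == "cox":
        t_event = rng.exponential(1.0 / (spec.baseline_hazard * np.exp(eta)))
        t_cens = rng.uniform(0.0, spec.censor_horizon, spec.n)
        t_cens = np.maximum(t_cens, 1e-9)
        frame["PHENO"] = (t_event <= t_cens).astype(int)
        frame["TIME"] = np.minimum(t_event, t_cens)
    else:
        raise ValueError(f"unknown family {spec.family!r}")

    kinds, levels, roles = {}, {}, {}
    unwanted: dict[str, set] = {}
    for j, name in enumerate(names):
        if j < spec.n_continuous:
            col = latent[name].to_numpy().copy()
            kinds[name] = "continuous"
        else:
            col = _quantile_levels(latent[name].to_numpy(), spec.categorical_levels)
            col = col.astype(object)
            kinds[name] = "categorical"
            levels[name] = [f"level{k + 1}" for k in range(spec.categorical_levels)]
            if spec.unwanted_rate > 0:
                mask = rng.random(spec.n) < spec.unwanted_rate
                col[mask] = UNWANTED_CODE
                unwanted[name] = {UNWANTED_CODE}
        if spec.missing_rate > 0:
            mask = rng.random(spec.n) < spec.missing_rate
            if kinds[name] == "continuous":
                col = col.astype(float)
                col[mask] = np.nan
            else:
                col[mask] = None
        frame[name] = col
        roles[name] = "exposure"
    frame["age"] = age
    frame["sex"] = sex
    roles["age"] = roles["sex"] = "covariate"
    kinds["age"] = kinds["sex"] = "continuous"

    cohort = CohortTable(frame, spec.family, roles, kinds, levels).validate()
    return SyntheticCohort(cohort, spec, unwanted, latent, eta)


# ---------------------------------------------------------------------------
# shipped fixtures
# ---------------------------------------------------------------------------

FIXTURE_SPECS = {
    "lm": TruthSpec(n=250, n_continuous=4, n_categorical=2, family="lm",
                    effects={"exp01": 0.4, "exp02": 0.4, "cat01": 0.3},
                    seed=101),
    "logistic": TruthSpec(n=250, n_continuous=4, n_categorical=2,
                          family="logistic", intercept=-1.0,
                          effects={"exp01": 0.5, "exp02": 0.5, "cat01": 0.4},
                          seed=102),
    "cox": TruthSpec(n=250, n_continuous=4, n_categorical=2, family="cox",
                     effects={"exp01": 0.5, "exp02": 0.5},
                     baseline_hazard=0.08, seed=103),
    "lm_interactions": TruthSpec(n=250, n_continuous=4, n_categorical=0,
                                 family="lm",
                                 effects={"exp01": 0.5, "exp02": 0.5},
                                 interaction_effects={("exp01", "exp02"): 0.5},
                                 seed=104),
}


def package_fixtures(out_dir: str) -> dict[str, str]:
    """Write the small deterministic CSV fixtures plus a YAML manifest of
    their generating specs; regenerating from the manifest seeds reproduces
    the files exactly."""
    import os

    from .cohort import write_cohort
    os.makedirs(out_dir, exist_ok=True)
    paths = {}
    manifest = {}
    for name, spec in FIXTURE_SPECS.items():
        syn = generate_cohort(spec)
        path = os.path.join(out_dir, f"{name}.csv")
        write_cohort(syn.cohort, path)
        paths[name] = path
        manifest[name] = yaml.safe_load(spec.to_yaml())
        manifest[name]["interaction_effects"] = {
            " * ".join(k): v for k, v in spec.interaction_effects.items()}
    with open(os.path.join(out_dir, "manifest.yaml"), "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return paths
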