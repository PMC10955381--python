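"""Synthetic cross-site survey generator with known ground truth.

Structural equations follow the package's causal graph: sex and age are
exogenous; education depends on both; children on education and age; food
insecurity on sex, age, education and children; both ordinal religiosity
outcomes on everything, through the same monotonic cumulative-logit form
used by the analysis model.  An optional latent binary "education type"
can act on religiosity alone or also on food insecurity, reproducing the
unmeasured-confounder scenarios.

Because every structural equation is known, the generator doubles as a
g-formula oracle: :func:`true_marginal_probs` evaluates the exact average
potential-outcome category probabilities for any hypothetical exposure
level, against which the model-based pipeline is validated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from . import constants as C
from .model import category_probs, mo

__all__ = [
    "ScmParams",
    "SimulationError",
    "simulate_population",
    "inject_missingness",
    "true_marginal_probs",
    "true_site_effects",
    "SCHEMA_COLUMNS",
]

SCHEMA_COLUMNS = (
    "site", "sex", "age", "education", "children", "food_insecure",
    "think_freq", "ritual_freq",
)
EXPOSURES = ("food_insecure", "education")


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class ScmParams:
    """Ground-truth structural-equation parameters.

    Monotonic effects are parameterized exactly as in the analysis model:
    a per-increment coefficient times a simplex of increment shares over
    the predictor's domain.
    """

    n_sites: int = C.DEFAULT_N_SITES
    n_per_site: int = C.DEFAULT_N_PER_SITE
    seed: int = 0

    beta_sex_on_y: float = C.DEFAULT_BETA_SEX_ON_Y
    beta_m_on_y: float = C.DEFAULT_BETA_M_ON_Y
    beta_edu_on_y: float = C.DEFAULT_BETA_EDU_ON_Y
    beta_age_on_y: float = C.DEFAULT_BETA_AGE_ON_Y
    beta_children_on_y: float = C.DEFAULT_BETA_CHILDREN_ON_Y

    food_insecurity_coefs: tuple = C.DEFAULT_FOOD_INSECURITY_COEFS
    children_rate_coefs: tuple = C.DEFAULT_CHILDREN_RATE_COEFS
    education_coefs: tuple = C.DEFAULT_EDUCATION_COEFS
    age_mean_frac: float = C.DEFAULT_AGE_MEAN_FRAC

    edu_simplex: tuple = C.DEFAULT_EDU_SIMPLEX
    age_simplex: tuple = C.DEFAULT_AGE_SIMPLEX
    children_simplex: tuple = C.DEFAULT_CHILDREN_SIMPLEX

    cutpoints: tuple = C.DEFAULT_CUTPOINTS
    site_effect_sd: float = C.DEFAULT_SITE_EFFECT_SD

    education_type_effect: float = C.DEFAULT_EDUCATION_TYPE_EFFECT
    education_type_food_effect: float = C.DEFAULT_EDUCATION_TYPE_FOOD_EFFECT
    education_type_prevalence: float = C.DEFAULT_EDUCATION_TYPE_PREVALENCE

    def __post_init__(self) -> None:
        if self.n_sites < 1 or self.n_per_site < 1:
            raise SimulationError("n_sites and n_per_site must be >= 1")
        for name in ("edu_simplex", "age_simplex", "children_simplex"):
            z = np.asarray(getattr(self, name), dtype=float)
            if z.size < 1 or np.any(z < 0) or abs(z.sum() - 1.0) > 1e-9:
                raise SimulationError(
                    f"{name} must be nonnegative and sum to 1"
                )
        k = np.asarray(self.cutpoints, dtype=float)
        if np.any(np.diff(k) <= 0):
            raise SimulationError("cutpoints must be strictly increasing")
        if self.site_effect_sd < 0:
            raise SimulationError("site_effect_sd must be nonnegative")
        if not 0 <= self.education_type_prevalence <= 1:
            raise SimulationError("education_type_prevalence must be in [0,1]")
        if not 0 < self.age_mean_frac < 1:
            raise SimulationError("age_mean_frac must be in (0,1)")

    @property
    def d_education(self) -> int:
        return len(self.edu_simplex)

    @property
    def d_age(self) -> int:
        return len(self.age_simplex)

    @property
    def d_children(self) -> int:
        return len(self.children_simplex)

    @property
    def site_labels(self) -> tuple:
        return tuple(f"site{i + 1:02d}" for i in range(self.n_sites))

    # flat key=value config round trip ------------------------------------
    def to_config(self) -> dict:
        out = {}
        for name, value in self.__dict__.items():
            out[name] = list(value) if isinstance(value, tuple) else value
        return out

    @classmethod
    def from_config(cls, mapping) -> "ScmParams":
        kwargs = {}
        for f in cls.__dataclass_fields__:
            if f in mapping:
                v = mapping[f]
                kwargs[f] = tuple(v) if isinstance(v, (list, tuple)) else v
        return cls(**kwargs)


def _streams(params: ScmParams):
    """Fixed spawning order so components are independently reproducible."""
    root = np.random.SeedSequence(params.seed)
    kids = root.spawn(4)
    return {
        "sites": np.random.default_rng(kids[0]),
        "edu_type": np.random.default_rng(kids[1]),
        "covariates": np.random.default_rng(kids[2]),
        "outcomes": np.random.default_rng(kids[3]),
    }


def true_site_effects(params: ScmParams) -> np.ndarray:
    """The per-site intercept shifts implied by the seed (length n_sites)."""
    rng = np.random.default_rng(np.random.SeedSequence(params.seed).spawn(4)[0])
    return rng.normal(0.0, params.site_effect_sd, size=params.n_sites)


def _true_xi(params: ScmParams, *, site_effect, sex, food, edu, age_inc,
             children, edu_type) -> np.ndarray:
    moE = mo(np.asarray(edu), params.edu_simplex)
    moA = mo(np.asarray(age_inc), params.age_simplex)
    moC = mo(np.asarray(children), params.children_simplex)
    return (
        np.asarray(site_effect, dtype=float)
        + params.beta_sex_on_y * np.asarray(sex)
        + params.beta_m_on_y * np.asarray(food)
        + params.beta_edu_on_y * moE
        + params.beta_age_on_y * moA
        + params.beta_children_on_y * moC
        + params.education_type_effect * np.asarray(edu_type)
    )


def _draw_categorical(rng, probs: np.ndarray) -> np.ndarray:
    """Sample 1-based categories from per-row probability vectors."""
    cum = np.cumsum(probs, axis=-1)
    u = rng.uniform(size=probs.shape[:-1])
    return 1 + np.sum(u[..., None] > cum[..., :-1], axis=-1)


def simulate_population(params: ScmParams) -> pd.DataFrame:
    """Generate one cross-site survey table; deterministic given the seed.

    Returns the public schema columns plus a private ``_edu_type`` column
    holding the latent education-type indicator (dropped by the CSV
    writer); per-site intercepts are recoverable via
    :func:`true_site_effects`.
    """
    rng = _streams(params)
    n = params.n_sites * params.n_per_site
    site_idx = np.repeat(np.arange(params.n_sites), params.n_per_site)
    site_effect = true_site_effects(params)[site_idx]

    edu_type = (
        rng["edu_type"].uniform(size=n) < params.education_type_prevalence
    ).astype(np.int64)

    cov = rng["covariates"]
    sex = cov.integers(0, 2, size=n)
    age_inc = cov.binomial(params.d_age, params.age_mean_frac, size=n)
    b0, b1, b2 = params.education_coefs
    edu_p = expit(b0 + b1 * sex + b2 * age_inc)
    edu = cov.binomial(params.d_education, edu_p)
    c0, c_edu, c_age = params.children_rate_coefs
    lam = np.exp(c0 + c_edu * edu + c_age * age_inc)
    children = np.minimum(cov.poisson(lam), params.d_children)
    f0, f_sex, f_age, f_edu, f_child = params.food_insecurity_coefs
    food_logit = (
        f0 + f_sex * sex + f_age * age_inc + f_edu * edu + f_child * children
        + params.education_type_food_effect * edu_type
    )
    food = (cov.uniform(size=n) < expit(food_logit)).astype(np.int64)

    xi = _true_xi(
        params, site_effect=site_effect, sex=sex, food=food, edu=edu,
        age_inc=age_inc, children=children, edu_type=edu_type,
    )
    probs = category_probs(xi, np.asarray(params.cutpoints, dtype=float))
    out_rng = rng["outcomes"]
    think = _draw_categorical(out_rng, probs)
    ritual = _draw_categorical(out_rng, probs)

    labels = np.asarray(params.site_labels)
    return pd.DataFrame({
        "site": labels[site_idx],
        "sex": sex,
        "age": C.AGE_MIN + age_inc,
        "education": edu,
        "children": children,
        "food_insecure": food,
        "think_freq": think,
        "ritual_freq": ritual,
        "_edu_type": edu_type,
    })


def inject_missingness(table: pd.DataFrame, rate: float,
                       seed: int) -> pd.DataFrame:
    """Blank each public cell independently with probability ``rate`` (MCAR)."""
    if not 0 <= rate < 1:
        raise SimulationError("missingness rate must be in [0, 1)")
    out = table.copy()
    if rate == 0:
        return out
    rng = np.random.default_rng(seed)
    for col in SCHEMA_COLUMNS:
        if col not in out.columns:
            continue
        mask = rng.uniform(size=len(out)) < rate
        if mask.any():
            if out[col].dtype.kind in "iu":
                out[col] = out[col].astype(float)
            out.loc[mask, col] = np.nan
    return out


def _exposure_arrays(params, table, exposure, level):
    if exposure not in EXPOSURES:
        raise SimulationError(f"unknown exposure {exposure!r}")
    if exposure == "food_insecure":
        if level not in (0, 1):
            raise SimulationError("food_insecure level must be 0 or 1")
    else:
        if not 0 <= level <= params.d_education:
            raise SimulationError(
                f"education level outside [0, {params.d_education}]"
            )
    food = table["food_insecure"].to_numpy(dtype=float)
    edu = table["education"].to_numpy(dtype=float)
    if exposure == "food_insecure":
        food = np.full(len(table), float(level))
    else:
        edu = np.full(len(table), float(level))
    return food.astype(np.int64), edu.astype(np.int64)


def true_marginal_probs(params: ScmParams, table: pd.DataFrame,
                        exposure: str, level) -> np.ndarray:
    """Exact g-formula category probabilities under do(exposure = level).

    Evaluates the generator's own structural outcome equation for every
    individual with the exposure forced to ``level`` and all remaining
    covariates (and latent inputs) held at their realized values, then
    averages.  No outcome sampling is involved.
    """
    required = ("site", "sex", "age", "education", "children",
                "food_insecure")
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise SimulationError(f"table missing column(s): {missing}")
    if table[list(required)].isna().any().any():
        raise SimulationError("true_marginal_probs requires complete cases")
    food, edu = _exposure_arrays(params, table, exposure, level)

    label_to_idx = {lbl: i for i, lbl in enumerate(params.site_labels)}
    try:
        site_idx = table["site"].map(label_to_idx).to_numpy(dtype=np.int64)
    except (TypeError, ValueError):
        raise SimulationError("table has site labels unknown to params")
    site_effect = true_site_effects(params)[site_idx]

    if "_edu_type" in table.columns:
        edu_type = table["_edu_type"].to_numpy(dtype=np.int64)
    else:
        edu_type = np.zeros(len(table), dtype=np.int64)

    xi = _true_xi(
        params,
        site_effect=site_effect,
        sex=table["sex"].to_numpy(dtype=float),
        food=food,
        edu=edu,
        age_inc=table["age"].to_numpy(dtype=np.int64) - C.AGE_MIN,
        children=table["children"].to_numpy(dtype=np.int64),
        edu_type=edu_type,
    )
    probs = category_probs(xi, np.asarray(params.cutpoints, dtype=float))
    return probs.mean(axis=0)
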