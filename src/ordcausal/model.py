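"""Multilevel Bayesian cumulative-logit regression with monotonic
ordinal predictors and site-varying effects.

The observation model for an ordinal response K_i in 1..K is

    P(K_i = k) = logistic(kappa_k - xi_i) - logistic(kappa_{k-1} - xi_i)

with strictly increasing cutpoints ``kappa`` and the linear predictor

    xi_i = a[site] + (b_sex + u_sex[site]) * S_i
         + (b_food + u_food[site]) * M_i
         + (b_edu + u_edu[site]) * mo(E_i, zeta_edu)
         + (b_age + u_age[site]) * mo(A_i - A_min, zeta_age)
         + (b_children + u_children[site]) * mo(C_i, zeta_children)

where ``mo`` is the monotonic transform: ``mo(x, zeta) = D * sum(zeta[:x])``
for a simplex ``zeta`` of length D, so each scalar coefficient reads as the
average difference between adjacent predictor levels and the full-range
effect equals coefficient * D.

Cutpoints are shared across sites; site heterogeneity enters through an
intercept offset plus an offset on every coefficient, drawn from a joint
zero-mean distribution with per-effect scales (Exponential prior) and an
LKJ-distributed correlation matrix.  Simplexes are shared across sites.
Fitting is full MCMC via the package's NUTS implementation with a
non-centred parameterization of the site effects.
"""

from __future__ import annotations

import hashlib
import io
import json
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from ._nuts import NutsConfig, SamplingError, sample_chain
from ._posterior import (
    J_EFFECTS,
    DesignData,
    OrdinalPosterior,
    cholesky_from_cpc,
    lkj_cpc_shapes,
    simplex_from_unconstrained,
)

__all__ = [
    "ModelSpec",
    "PosteriorDraws",
    "SingleDraw",
    "DiagnosticsReport",
    "ModelError",
    "SamplingError",
    "mo",
    "category_probs",
    "linear_predictor",
    "log_likelihood",
    "prior_predictive",
    "sample_prior_params",
    "fit",
    "diagnostics",
]

OUTCOME_COLUMNS = ("think_freq", "ritual_freq")
BETA_NAMES = ("sex", "food", "edu", "age", "children")
EFFECT_NAMES = ("intercept",) + BETA_NAMES
MODEL_COLUMNS = ("site", "sex", "age", "education", "children", "food_insecure")


class ModelError(ValueError):
    """Invalid model inputs (schema, ranges, missingness)."""


@dataclass(frozen=True)
class ModelSpec:
    """Structure and prior settings for one outcome's regression."""

    outcome: str
    d_age: int
    d_children: int
    n_categories: int = 5
    d_education: int = 30
    age_min: int = 17
    threshold_scale: float = 10.0
    coef_scale: float = 0.5
    dirichlet_alpha: float = 2.0
    sd_rate: float = 1.0
    lkj_shape: float = 4.0

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOME_COLUMNS:
            raise ModelError(f"unknown outcome {self.outcome!r}")
        if self.n_categories < 2:
            raise ModelError("need at least two outcome categories")
        for name in ("d_education", "d_age", "d_children"):
            if getattr(self, name) < 1:
                raise ModelError(f"{name} must be >= 1")
        for name in ("threshold_scale", "coef_scale", "dirichlet_alpha",
                     "sd_rate", "lkj_shape"):
            if getattr(self, name) <= 0:
                raise ModelError(f"{name} must be positive")

    @classmethod
    def from_table(cls, table: pd.DataFrame, outcome: str,
                   **overrides) -> "ModelSpec":
        """Derive monotonic-predictor domains from observed data.

        Education keeps the fixed 0..30-year domain; the age domain is the
        observed range above the observed minimum and the children domain
        the observed maximum count.
        """
        age = pd.to_numeric(table["age"], errors="coerce").dropna()
        children = pd.to_numeric(table["children"], errors="coerce").dropna()
        if age.empty or children.empty:
            raise ModelError("table has no usable age/children values")
        defaults = dict(
            outcome=outcome,
            age_min=int(age.min()),
            d_age=max(int(age.max() - age.min()), 1),
            d_children=max(int(children.max()), 1),
        )
        defaults.update(overrides)
        return cls(**defaults)

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "d_age": self.d_age,
            "d_children": self.d_children,
            "n_categories": self.n_categories,
            "d_education": self.d_education,
            "age_min": self.age_min,
            "threshold_scale": self.threshold_scale,
            "coef_scale": self.coef_scale,
            "dirichlet_alpha": self.dirichlet_alpha,
            "sd_rate": self.sd_rate,
            "lkj_shape": self.lkj_shape,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelSpec":
        return cls(**dict(d))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


# ---------------------------------------------------------------------------
# Elementary model functions
# ---------------------------------------------------------------------------

def _check_simplex(zeta: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    zeta = np.asarray(zeta, dtype=float)
    if zeta.ndim != 1 or zeta.size < 1:
        raise ModelError("simplex must be a 1-d vector")
    if np.any(zeta < -tol) or abs(zeta.sum() - 1.0) > tol:
        raise ModelError("simplex weights must be nonnegative and sum to 1")
    return zeta


def mo(x, zeta) -> np.ndarray | float:
    """Monotonic transform: ``mo(x) = D * sum(zeta[:x])``, ``mo(0) = 0``.

    ``x`` counts predictor increments (0..D); ``zeta`` is a simplex of
    length D.  With this scaling, a coefficient attached to ``mo`` is the
    average adjacent-level difference and ``mo(D) = D`` exactly.
    """
    zeta = _check_simplex(zeta)
    d = zeta.size
    xa = np.asarray(x)
    if np.any(xa < 0) or np.any(xa > d):
        raise ModelError(f"monotonic level out of range [0, {d}]")
    table = d * np.concatenate(([0.0], np.cumsum(zeta)))
    table[-1] = d  # exact endpoint despite accumulated rounding
    out = table[np.asarray(xa, dtype=np.int64)]
    return float(out) if np.isscalar(x) or xa.ndim == 0 else out


def category_probs(xi, kappa) -> np.ndarray:
    """Ordered-logit category probabilities.

    ``P(k) = logistic(kappa_k - xi) - logistic(kappa_{k-1} - xi)`` with
    implicit boundary cutpoints at -inf and +inf.  ``xi`` may be any
    shape; ``kappa`` must be strictly increasing along its last axis and
    broadcast against ``xi``'s shape.  Returns probabilities with a
    trailing axis of length K.
    """
    kappa = np.asarray(kappa, dtype=float)
    if np.any(np.diff(kappa, axis=-1) <= 0):
        raise ModelError("cutpoints must be strictly increasing")
    xi_arr = np.asarray(xi, dtype=float)
    cum = expit(kappa - xi_arr[..., None])
    shape = cum.shape[:-1]
    zeros = np.zeros(shape + (1,))
    ones = np.ones(shape + (1,))
    probs = np.diff(np.concatenate([zeros, cum, ones], axis=-1), axis=-1)
    return probs


# ---------------------------------------------------------------------------
# Posterior containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SingleDraw:
    """One posterior (or ground-truth) parameter configuration."""

    kappa: np.ndarray                  # (K-1,)
    beta: np.ndarray                   # (5,) order: sex, food, edu, age, children
    zeta_edu: np.ndarray
    zeta_age: np.ndarray
    zeta_children: np.ndarray
    site_effects: np.ndarray           # (6, S) rows follow EFFECT_NAMES
    sites: tuple
    sigma: Optional[np.ndarray] = None
    corr: Optional[np.ndarray] = None
    divergent: bool = False

    def site_index(self, site) -> int:
        try:
            return self.sites.index(str(site))
        except ValueError:
            raise ModelError(f"unknown site {site!r}") from None

    def coef(self, name: str) -> float:
        return float(self.beta[BETA_NAMES.index(name)])


@dataclass
class PosteriorDraws:
    """Stacked posterior draws for one fitted outcome."""

    spec: ModelSpec
    sites: tuple
    kappa: np.ndarray            # (m, K-1)
    beta: np.ndarray             # (m, 5)
    zeta_edu: np.ndarray         # (m, D_E)
    zeta_age: np.ndarray         # (m, D_A)
    zeta_children: np.ndarray    # (m, D_C)
    sigma: np.ndarray            # (m, 6)
    corr: np.ndarray             # (m, 6, 6)
    site_effects: np.ndarray     # (m, 6, S)
    divergent: np.ndarray        # (m,)
    chain_ids: np.ndarray        # (m,)
    seed: Optional[int] = None

    @property
    def n_draws(self) -> int:
        return self.kappa.shape[0]

    @property
    def n_chains(self) -> int:
        return int(len(np.unique(self.chain_ids)))

    def draw(self, i: int) -> SingleDraw:
        return SingleDraw(
            kappa=self.kappa[i],
            beta=self.beta[i],
            zeta_edu=self.zeta_edu[i],
            zeta_age=self.zeta_age[i],
            zeta_children=self.zeta_children[i],
            site_effects=self.site_effects[i],
            sites=self.sites,
            sigma=self.sigma[i],
            corr=self.corr[i],
            divergent=bool(self.divergent[i]),
        )

    def thin(self, max_draws: int) -> "PosteriorDraws":
        """Evenly subsample down to at most ``max_draws`` draws."""
        m = self.n_draws
        if m <= max_draws:
            return self
        idx = np.linspace(0, m - 1, max_draws).round().astype(int)
        return PosteriorDraws(
            spec=self.spec, sites=self.sites,
            kappa=self.kappa[idx], beta=self.beta[idx],
            zeta_edu=self.zeta_edu[idx], zeta_age=self.zeta_age[idx],
            zeta_children=self.zeta_children[idx],
            sigma=self.sigma[idx], corr=self.corr[idx],
            site_effects=self.site_effects[idx],
            divergent=self.divergent[idx], chain_ids=self.chain_ids[idx],
            seed=self.seed,
        )

    # -- columnar serialization -------------------------------------------

    def _column_frame(self) -> pd.DataFrame:
        cols: dict[str, np.ndarray] = {"chain": self.chain_ids,
                                       "divergent": self.divergent.astype(int)}
        for j in range(self.kappa.shape[1]):
            cols[f"kappa.{j + 1}"] = self.kappa[:, j]
        for j, nm in enumerate(BETA_NAMES):
            cols[f"b_{nm}"] = self.beta[:, j]
        for label, arr in (("zeta_edu", self.zeta_edu),
                           ("zeta_age", self.zeta_age),
                           ("zeta_children", self.zeta_children)):
            for j in range(arr.shape[1]):
                cols[f"{label}.{j + 1}"] = arr[:, j]
        for j, nm in enumerate(EFFECT_NAMES):
            cols[f"sigma_{nm}"] = self.sigma[:, j]
        for i in range(J_EFFECTS):
            for j in range(i):
                cols[f"corr.{i + 1}.{j + 1}"] = self.corr[:, i, j]
        for j, nm in enumerate(EFFECT_NAMES):
            for s in range(len(self.sites)):
                cols[f"u_{nm}.{s + 1}"] = self.site_effects[:, j, s]
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        meta = {
            "format": "ordcausal-draws-v1",
            "seed": self.seed,
            "sites": list(self.sites),
            "spec": self.spec.to_dict(),
            "spec_hash": self.spec.config_hash(),
            "n_chains": self.n_chains,
        }
        frame = self._column_frame()
        with open(path, "w") as fh:
            fh.write("# " + json.dumps(meta, sort_keys=True) + "\n")
            frame.to_csv(fh, index=False, lineterminator="\n")

    @classmethod
    def from_csv(cls, path) -> "PosteriorDraws":
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("#"):
                raise ModelError("draws file lacks the metadata header")
            meta = json.loads(header[1:].strip())
            frame = pd.read_csv(io.StringIO(fh.read()))
        spec = ModelSpec.from_dict(meta["spec"])
        sites = tuple(meta["sites"])
        m = len(frame)
        K = spec.n_categories

        def block(prefix, count):
            return np.column_stack(
                [frame[f"{prefix}.{j + 1}"].to_numpy() for j in range(count)]
            )

        corr = np.tile(np.eye(J_EFFECTS), (m, 1, 1))
        for i in range(J_EFFECTS):
            for j in range(i):
                v = frame[f"corr.{i + 1}.{j + 1}"].to_numpy()
                corr[:, i, j] = v
                corr[:, j, i] = v
        site_effects = np.empty((m, J_EFFECTS, len(sites)))
        for j, nm in enumerate(EFFECT_NAMES):
            for s in range(len(sites)):
                site_effects[:, j, s] = frame[f"u_{nm}.{s + 1}"].to_numpy()
        return cls(
            spec=spec,
            sites=sites,
            kappa=block("kappa", K - 1),
            beta=np.column_stack(
                [frame[f"b_{nm}"].to_numpy() for nm in BETA_NAMES]
            ),
            zeta_edu=block("zeta_edu", spec.d_education),
            zeta_age=block("zeta_age", spec.d_age),
            zeta_children=block("zeta_children", spec.d_children),
            sigma=np.column_stack(
                [frame[f"sigma_{nm}"].to_numpy() for nm in EFFECT_NAMES]
            ),
            corr=corr,
            site_effects=site_effects,
            divergent=frame["divergent"].to_numpy().astype(bool),
            chain_ids=frame["chain"].to_numpy().astype(int),
            seed=meta.get("seed"),
        )


# ---------------------------------------------------------------------------
# Predictor evaluation
# ---------------------------------------------------------------------------

_REQUIRED_FIELDS = MODEL_COLUMNS


def _field(record, name):
    try:
        v = record[name]
    except (KeyError, IndexError):
        raise ModelError(f"record missing field {name!r}") from None
    if v is None or (isinstance(v, float) and np.isnan(v)):
        raise ModelError(f"record has missing value for {name!r}")
    return v


def linear_predictor(record: Mapping, draw: SingleDraw,
                     spec: ModelSpec) -> float:
    """Evaluate xi for a single complete record under one draw."""
    s_idx = draw.site_index(_field(record, "site"))
    sex = float(_field(record, "sex"))
    foodins = float(_field(record, "food_insecure"))
    edu = int(_field(record, "education"))
    age = int(_field(record, "age"))
    child = int(_field(record, "children"))
    age_idx = age - spec.age_min
    if not 0 <= age_idx <= spec.d_age:
        raise ModelError(
            f"age {age} outside modelled range "
            f"[{spec.age_min}, {spec.age_min + spec.d_age}]"
        )
    u = draw.site_effects[:, s_idx]
    return float(
        u[0]
        + (draw.beta[0] + u[1]) * sex
        + (draw.beta[1] + u[2]) * foodins
        + (draw.beta[2] + u[3]) * mo(edu, draw.zeta_edu)
        + (draw.beta[3] + u[4]) * mo(age_idx, draw.zeta_age)
        + (draw.beta[4] + u[5]) * mo(child, draw.zeta_children)
    )


def _mo_tables(draws_zeta: np.ndarray, d: int) -> np.ndarray:
    """Batch mo lookup tables, shape (m, d+1)."""
    m = draws_zeta.shape[0]
    tables = np.concatenate(
        [np.zeros((m, 1)), d * np.cumsum(draws_zeta, axis=1)], axis=1
    )
    tables[:, -1] = d
    return tables


def batch_linear_predictor(
    *, beta, site_effects, zeta_edu, zeta_age, zeta_children, spec,
    site_idx, sex, food, edu, age_idx, child,
) -> np.ndarray:
    """xi for a batch of draws x individuals, shape (m, n).

    Draw-level inputs carry a leading draw axis; individual-level inputs
    are 1-d arrays of equal length.
    """
    moE = _mo_tables(zeta_edu, spec.d_education)
    moA = _mo_tables(zeta_age, spec.d_age)
    moC = _mo_tables(zeta_children, spec.d_children)
    m = beta.shape[0]
    coefs = np.concatenate([np.zeros((m, 1)), beta], axis=1)[:, :, None] \
        + site_effects                             # (m, 6, S)
    csel = coefs[:, :, site_idx]                   # (m, 6, n)
    return (
        csel[:, 0]
        + csel[:, 1] * sex
        + csel[:, 2] * food
        + csel[:, 3] * moE[:, edu]
        + csel[:, 4] * moA[:, age_idx]
        + csel[:, 5] * moC[:, child]
    )


def _design_from_table(table: pd.DataFrame, spec: ModelSpec,
                       sites: Optional[Sequence[str]] = None,
                       require_outcome: bool = True) -> DesignData:
    cols = list(MODEL_COLUMNS) + ([spec.outcome] if require_outcome else [])
    missing_cols = [c for c in cols if c not in table.columns]
    if missing_cols:
        raise ModelError(f"table missing column(s): {missing_cols}")
    sub = table[cols]
    if sub.isna().any().any():
        bad = sub.columns[sub.isna().any()].tolist()
        raise ModelError(
            f"table contains missing values in {bad}; apply complete-case "
            "filtering first"
        )
    site_labels = sub["site"].astype(str).to_numpy()
    if sites is None:
        sites = tuple(sorted(set(site_labels)))
    else:
        sites = tuple(sites)
        unknown = set(site_labels) - set(sites)
        if unknown:
            raise ModelError(f"unknown site(s): {sorted(unknown)}")
    lookup = {s: i for i, s in enumerate(sites)}
    site_idx = np.array([lookup[s] for s in site_labels])

    def intcol(name, lo, hi):
        v = pd.to_numeric(sub[name]).to_numpy()
        iv = v.astype(np.int64)
        if np.any(iv != v):
            raise ModelError(f"column {name!r} must be integer-valued")
        if np.any(iv < lo) or np.any(iv > hi):
            raise ModelError(f"column {name!r} outside [{lo}, {hi}]")
        return iv

    sex = intcol("sex", 0, 1).astype(float)
    food = intcol("food_insecure", 0, 1).astype(float)
    edu = intcol("education", 0, spec.d_education)
    age = intcol("age", spec.age_min, spec.age_min + spec.d_age)
    child = intcol("children", 0, spec.d_children)
    if require_outcome:
        outcome = intcol(spec.outcome, 1, spec.n_categories)
    else:
        outcome = np.ones(len(sub), dtype=np.int64)
    return DesignData(
        site_idx=site_idx, sex=sex, food=food, edu=edu,
        age_idx=age - spec.age_min, child=child, outcome=outcome,
        n_sites=len(sites), sites=sites,
    )


def log_likelihood(table: pd.DataFrame, draw: SingleDraw,
                   spec: ModelSpec) -> float:
    """Sum of log ordered-logit probabilities at the observed outcomes."""
    if len(table) == 0:
        return 0.0
    design = _design_from_table(table, spec, sites=draw.sites)
    xi = batch_linear_predictor(
        beta=draw.beta[None], site_effects=draw.site_effects[None],
        zeta_edu=draw.zeta_edu[None], zeta_age=draw.zeta_age[None],
        zeta_children=draw.zeta_children[None], spec=spec,
        site_idx=design.site_idx, sex=design.sex, food=design.food,
        edu=design.edu, age_idx=design.age_idx, child=design.child,
    )[0]
    probs = category_probs(xi, draw.kappa)
    picked = probs[np.arange(len(xi)), design.outcome - 1]
    return float(np.sum(np.log(np.maximum(picked, 1e-300))))


# ---------------------------------------------------------------------------
# Prior sampling
# ---------------------------------------------------------------------------

def sample_prior_params(spec: ModelSpec, n_sites: int, n_draws: int,
                        rng: np.random.Generator) -> dict:
    """Draw parameter sets from the stated priors.

    Cutpoints are sorted Normal(0, threshold_scale) draws; the correlation
    matrix is sampled through its canonical partial correlations, which
    are independent scaled Betas under the LKJ prior.
    """
    m = n_draws
    K = spec.n_categories
    kappa = np.sort(
        rng.normal(0.0, spec.threshold_scale, size=(m, K - 1)), axis=1
    )
    beta = rng.normal(0.0, spec.coef_scale, size=(m, len(BETA_NAMES)))
    alpha = spec.dirichlet_alpha

    def simplex(d):
        return rng.dirichlet(np.full(d, alpha), size=m)

    sigma = rng.exponential(1.0 / spec.sd_rate, size=(m, J_EFFECTS))
    shapes = lkj_cpc_shapes(J_EFFECTS, spec.lkj_shape)
    cpc = 2.0 * rng.beta(shapes, shapes, size=(m, shapes.size)) - 1.0
    L = cholesky_from_cpc(cpc, J_EFFECTS)
    Z = rng.standard_normal(size=(m, J_EFFECTS, n_sites))
    site_effects = (sigma[:, :, None] * L) @ Z
    return {
        "kappa": kappa,
        "beta": beta,
        "zeta_edu": simplex(spec.d_education),
        "zeta_age": simplex(spec.d_age),
        "zeta_children": simplex(spec.d_children),
        "sigma": sigma,
        "corr": L @ np.swapaxes(L, -1, -2),
        "site_effects": site_effects,
    }


def prior_predictive(spec: ModelSpec, covariates: pd.DataFrame,
                     n_draws: int, seed: int):
    """Simulate outcomes for a covariate table under the prior.

    Returns ``(outcomes, params)`` where ``outcomes`` has shape
    ``(n_draws, n_rows)`` with values in 1..K and ``params`` is the dict of
    prior parameter draws used.
    """
    if n_draws < 1:
        raise ModelError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    design = _design_from_table(spec=spec, table=covariates,
                                require_outcome=False)
    params = sample_prior_params(spec, design.n_sites, n_draws, rng)
    xi = batch_linear_predictor(
        beta=params["beta"], site_effects=params["site_effects"],
        zeta_edu=params["zeta_edu"], zeta_age=params["zeta_age"],
        zeta_children=params["zeta_children"], spec=spec,
        site_idx=design.site_idx, sex=design.sex, food=design.food,
        edu=design.edu, age_idx=design.age_idx, child=design.child,
    )
    # sorted normal cutpoints may tie at machine precision; nudge if needed
    kappa = params["kappa"]
    eps = 1e-9 * np.arange(kappa.shape[1])
    cum = expit((kappa + eps)[:, None, :] - xi[:, :, None])
    u = rng.uniform(size=xi.shape)
    outcomes = 1 + np.sum(u[:, :, None] > cum, axis=-1)
    return outcomes, params


# ---------------------------------------------------------------------------
# Fitting and diagnostics
# ---------------------------------------------------------------------------

def fit(
    table: pd.DataFrame,
    spec: ModelSpec,
    *,
    chains: int = 4,
    warmup: int = 1000,
    draws: int = 1000,
    seed: int,
    target_accept: float = 0.8,
    max_treedepth: int = 10,
) -> PosteriorDraws:
    """Sample the posterior by NUTS.  Deterministic given data and seed."""
    design = _design_from_table(table, spec)
    if design.n_sites < 2:
        raise ModelError("site-varying effects require at least two sites")
    if chains < 1:
        raise ModelError("need at least one chain")
    post = OrdinalPosterior(design, spec)
    cfg = NutsConfig(
        warmup=warmup, draws=draws, target_accept=target_accept,
        max_treedepth=max_treedepth,
    )
    seeds = np.random.SeedSequence(seed).spawn(chains)
    all_draws = []
    all_div = []
    chain_ids = []
    for ci, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        theta0 = post.initial_position(rng)
        result = sample_chain(post.value_and_grad, theta0, rng, cfg)
        all_draws.append(result.draws)
        all_div.append(result.divergent)
        chain_ids.append(np.full(draws, ci))
    thetas = np.concatenate(all_draws, axis=0)
    divergent = np.concatenate(all_div)
    if divergent.all():
        raise SamplingError("all post-warmup transitions diverged")
    con = post.constrain(thetas)
    return PosteriorDraws(
        spec=spec,
        sites=design.sites,
        kappa=con["kappa"],
        beta=con["beta"],
        zeta_edu=con["zeta_edu"],
        zeta_age=con["zeta_age"],
        zeta_children=con["zeta_children"],
        sigma=con["sigma"],
        corr=con["corr"],
        site_effects=con["site_effects"],
        divergent=divergent,
        chain_ids=np.concatenate(chain_ids),
        seed=seed,
    )


@dataclass
class DiagnosticsReport:
    summary: pd.DataFrame
    n_divergent: int
    divergence_rate: float
    max_rhat: float
    flagged: list
    n_chains: int
    rhat_threshold: float = 1.01

    @property
    def ok(self) -> bool:
        if self.n_chains < 2:
            return self.divergence_rate < 0.05
        return (not self.flagged) and self.divergence_rate < 0.05

    def __str__(self) -> str:
        lines = [
            f"chains: {self.n_chains}",
            f"divergent transitions: {self.n_divergent} "
            f"({100 * self.divergence_rate:.2f}%)",
        ]
        if np.isnan(self.max_rhat):
            lines.append("rhat: unavailable (single chain)")
        else:
            lines.append(f"max split-rhat: {self.max_rhat:.4f}")
        if self.flagged:
            lines.append(f"flagged (rhat > {self.rhat_threshold}): "
                         + ", ".join(self.flagged))
        return "\n".join(lines)


def _scalar_param_arrays(draws: PosteriorDraws) -> dict:
    out = {}
    for j in range(draws.kappa.shape[1]):
        out[f"kappa.{j + 1}"] = draws.kappa[:, j]
    for j, nm in enumerate(BETA_NAMES):
        out[f"b_{nm}"] = draws.beta[:, j]
    for j, nm in enumerate(EFFECT_NAMES):
        out[f"sigma_{nm}"] = draws.sigma[:, j]
    return out


def diagnostics(draws: PosteriorDraws,
                rhat_threshold: float = 1.01) -> DiagnosticsReport:
    """Split-R-hat, bulk/tail effective sample sizes and divergence counts.

    Computed with arviz on the population-level scalar parameters.  With a
    single chain R-hat is omitted (with a warning) and only divergences
    are reported.
    """
    import arviz as az

    params = _scalar_param_arrays(draws)
    chains = np.unique(draws.chain_ids)
    n_chains = len(chains)
    per_chain = {
        nm: np.stack([v[draws.chain_ids == c] for c in chains])
        for nm, v in params.items()
    }
    rows = []
    if n_chains < 2:
        warnings.warn(
            "single chain: split-R-hat omitted", stacklevel=2
        )
        for nm, arr in per_chain.items():
            ds = az.convert_to_dataset({nm: arr})
            rows.append({
                "param": nm,
                "rhat": np.nan,
                "ess_bulk": float(az.ess(ds, method="bulk")[nm]),
                "ess_tail": float(az.ess(ds, method="tail")[nm]),
            })
    else:
        ds = az.convert_to_dataset(per_chain)
        rhat = az.rhat(ds)
        ess_bulk = az.ess(ds, method="bulk")
        ess_tail = az.ess(ds, method="tail")
        for nm in per_chain:
            rows.append({
                "param": nm,
                "rhat": float(rhat[nm]),
                "ess_bulk": float(ess_bulk[nm]),
                "ess_tail": float(ess_tail[nm]),
            })
    summary = pd.DataFrame(rows).set_index("param")
    n_div = int(draws.divergent.sum())
    max_rhat = float(summary["rhat"].max()) if n_chains >= 2 else float("nan")
    flagged = (
        summary.index[summary["rhat"] > rhat_threshold].tolist()
        if n_chains >= 2 else []
    )
    return DiagnosticsReport(
        summary=summary,
        n_divergent=n_div,
        divergence_rate=n_div / max(draws.n_draws, 1),
        max_rhat=max_rhat,
        flagged=flagged,
        n_chains=n_chains,
        rhat_threshold=rhat_threshold,
    )
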