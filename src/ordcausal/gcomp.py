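"""Counterfactual g-computation on fitted posterior draws.

Three steps: (1) for every posterior draw and individual, impute the
outcome-category probability vector under each hypothetical exposure
level, holding all other covariates at their observed values; (2) average
those vectors over individuals — pooled or within site — to obtain
marginal (standardized) probabilities per draw; (3) contrast exposure
levels on the draw scale and summarize with posterior means and central
intervals.

Probability vectors, not sampled outcomes, are carried through all three
steps, which removes an unnecessary Monte Carlo layer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import (
    ModelError,
    ModelSpec,
    PosteriorDraws,
    batch_linear_predictor,
    category_probs,
    _design_from_table,
)

__all__ = [
    "ExposureGrid",
    "CounterfactualSummary",
    "impute_potential_outcomes",
    "marginalize",
    "contrast",
]

EXPOSURES = ("food_insecure", "education")
DEFAULT_EDUCATION_LEVELS = (0, 5, 10, 15, 20, 25, 30)
POOLED_LABEL = "pooled"


@dataclass(frozen=True)
class ExposureGrid:
    """Hypothetical exposure levels for one focal predictor."""

    exposure: str
    levels: tuple

    def __post_init__(self) -> None:
        if self.exposure not in EXPOSURES:
            raise ModelError(f"unknown exposure {self.exposure!r}")
        object.__setattr__(self, "levels", tuple(self.levels))
        if len(self.levels) < 2:
            raise ModelError("grid needs at least two levels")
        if np.any(np.diff(self.levels) <= 0):
            raise ModelError("grid levels must be strictly increasing")

    @classmethod
    def food(cls) -> "ExposureGrid":
        return cls("food_insecure", (0, 1))

    @classmethod
    def education(cls, levels: Sequence = DEFAULT_EDUCATION_LEVELS
                  ) -> "ExposureGrid":
        return cls("education", tuple(levels))

    def validate_domain(self, spec: ModelSpec) -> None:
        if self.exposure == "food_insecure":
            if not set(self.levels) <= {0, 1}:
                raise ModelError("food_insecure levels must be 0/1")
        else:
            lo, hi = min(self.levels), max(self.levels)
            if lo < 0 or hi > spec.d_education:
                raise ModelError(
                    f"education levels outside [0, {spec.d_education}]"
                )

    def index_of(self, level) -> int:
        try:
            return self.levels.index(level)
        except ValueError:
            raise ModelError(f"level {level!r} not in grid") from None


@dataclass
class CounterfactualSummary:
    """Tidy posterior summaries of marginal counterfactual probabilities.

    ``table`` has columns (unit, exposure, level, category, mean, lower,
    upper); ``per_individual`` retains each individual's posterior-mean
    probability vector per level for figure reproduction.
    """

    table: pd.DataFrame
    interval: float
    exposure: str
    per_individual: Optional[pd.DataFrame] = None

    def to_csv(self, path, *, header_comment: Optional[str] = None) -> None:
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            self.table.to_csv(fh, index=False, lineterminator="\n")

    def per_individual_to_csv(self, path) -> None:
        if self.per_individual is None:
            raise ModelError("per-individual means were not retained")
        self.per_individual.to_csv(path, index=False, lineterminator="\n")


def impute_potential_outcomes(
    draws: PosteriorDraws,
    table: pd.DataFrame,
    grid: ExposureGrid,
    *,
    population_level: bool = False,
    batch_draws: int = 250,
) -> np.ndarray:
    """Per-draw, per-individual, per-level category probabilities.

    Returns an array of shape ``(n_draws, n_individuals, n_levels, K)``.
    With ``population_level`` the site offsets are zeroed, giving
    predictions for a generic (non-sampled) site as used by
    poststratification.
    """
    spec = draws.spec
    grid.validate_domain(spec)
    design = _design_from_table(table, spec, sites=draws.sites,
                                require_outcome=False)
    m, n, L, K = (draws.n_draws, design.n, len(grid.levels),
                  spec.n_categories)
    site_effects = draws.site_effects
    if population_level:
        site_effects = np.zeros_like(site_effects)
    out = np.empty((m, n, L, K))
    for li, level in enumerate(grid.levels):
        food = design.food
        edu = design.edu
        if grid.exposure == "food_insecure":
            food = np.full(n, float(level))
        else:
            edu = np.full(n, int(level), dtype=np.int64)
        for start in range(0, m, batch_draws):
            sl = slice(start, min(start + batch_draws, m))
            xi = batch_linear_predictor(
                beta=draws.beta[sl], site_effects=site_effects[sl],
                zeta_edu=draws.zeta_edu[sl], zeta_age=draws.zeta_age[sl],
                zeta_children=draws.zeta_children[sl], spec=spec,
                site_idx=design.site_idx, sex=design.sex, food=food,
                edu=edu, age_idx=design.age_idx, child=design.child,
            )
            out[sl, :, li, :] = category_probs(xi, draws.kappa[sl, None, :])
    return out


def _unit_groups(table: pd.DataFrame, by_site: bool):
    """Ordered (label, row-indices) pairs for marginalization units."""
    if not by_site:
        return [(POOLED_LABEL, np.arange(len(table)))]
    sites = table["site"].astype(str).to_numpy()
    groups = []
    for lbl in sorted(set(sites)):
        idx = np.flatnonzero(sites == lbl)
        if idx.size == 0:  # pragma: no cover - defensive
            warnings.warn(f"site {lbl!r} has no rows; omitted")
            continue
        groups.append((lbl, idx))
    return groups


def _interval_bounds(arr: np.ndarray, interval: float, axis=0):
    lo = (1.0 - interval) / 2.0
    return (
        np.quantile(arr, lo, axis=axis),
        np.quantile(arr, 1.0 - lo, axis=axis),
    )


def marginalize(
    potential: np.ndarray,
    table: pd.DataFrame,
    grid: ExposureGrid,
    *,
    by_site: bool = True,
    include_pooled: bool = True,
    interval: float = 0.95,
    keep_individual: bool = True,
) -> CounterfactualSummary:
    """Average imputed probabilities over individuals, then across draws.

    Per-site averages are the default unit (plus a pooled row set);
    summaries are the posterior mean and a central interval of the
    draw-level marginal probabilities.
    """
    m, n, L, K = potential.shape
    if len(table) != n:
        raise ModelError("table row count does not match potential outcomes")
    units = _unit_groups(table, by_site)
    if by_site and include_pooled:
        units = units + [(POOLED_LABEL, np.arange(n))]
    rows = []
    for lbl, idx in units:
        per_draw = potential[:, idx].mean(axis=1)  # (m, L, K)
        mean = per_draw.mean(axis=0)
        lower, upper = _interval_bounds(per_draw, interval)
        for li, level in enumerate(grid.levels):
            for k in range(K):
                rows.append({
                    "unit": lbl,
                    "exposure": grid.exposure,
                    "level": level,
                    "category": k + 1,
                    "mean": mean[li, k],
                    "lower": lower[li, k],
                    "upper": upper[li, k],
                })
    tidy = pd.DataFrame(rows)

    per_individual = None
    if keep_individual:
        indiv_mean = potential.mean(axis=0)  # (n, L, K)
        recs = []
        site_col = table["site"].astype(str).to_numpy()
        for li, level in enumerate(grid.levels):
            for k in range(K):
                recs.append(pd.DataFrame({
                    "individual": np.arange(n),
                    "site": site_col,
                    "exposure": grid.exposure,
                    "level": level,
                    "category": k + 1,
                    "mean": indiv_mean[:, li, k],
                }))
        per_individual = pd.concat(recs, ignore_index=True)
    return CounterfactualSummary(
        table=tidy, interval=interval, exposure=grid.exposure,
        per_individual=per_individual,
    )


def contrast(
    potential: np.ndarray,
    table: pd.DataFrame,
    grid: ExposureGrid,
    level_a,
    level_b,
    *,
    by_site: bool = True,
    include_pooled: bool = True,
    interval: float = 0.95,
) -> pd.DataFrame:
    """Per-category difference in marginal probabilities, level_b - level_a.

    Differences are taken draw by draw (never between summaries) and then
    summarized.  Identical levels return an all-zero contrast with a
    ``note`` column flagging the degenerate request.
    """
    ia = grid.index_of(level_a)
    ib = grid.index_of(level_b)
    m, n, L, K = potential.shape
    if len(table) != n:
        raise ModelError("table row count does not match potential outcomes")
    units = _unit_groups(table, by_site)
    if by_site and include_pooled:
        units = units + [(POOLED_LABEL, np.arange(n))]
    degenerate = ia == ib
    rows = []
    for lbl, idx in units:
        per_draw = potential[:, idx].mean(axis=1)  # (m, L, K)
        diff = per_draw[:, ib, :] - per_draw[:, ia, :]  # (m, K)
        mean = diff.mean(axis=0)
        lower, upper = _interval_bounds(diff, interval)
        for k in range(K):
            row = {
                "unit": lbl,
                "exposure": grid.exposure,
                "level_a": level_a,
                "level_b": level_b,
                "category": k + 1,
                "mean": mean[k],
                "lower": lower[k],
                "upper": upper[k],
            }
            if degenerate:
                row["note"] = "identical levels"
            rows.append(row)
    return pd.DataFrame(rows)
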