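"""Poststratification: re-weight counterfactual predictions to an
external target population described by a banded stratum table.

Strata are defined over banded model covariates (sex, age band, education
band, children band, food insecurity); band edges default to 10-year age
bands and 5-year education bands.  Site is marginalized out — the target
population is external to the sampled sites — so the potential-outcomes
array passed in should normally be computed with zero site offsets
(``impute_potential_outcomes(..., population_level=True)``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .gcomp import CounterfactualSummary, ExposureGrid, _interval_bounds
from .model import ModelError

__all__ = [
    "StrataTable",
    "DEFAULT_AGE_EDGES",
    "DEFAULT_EDUCATION_EDGES",
    "DEFAULT_CHILDREN_EDGES",
    "band_label",
    "assign_strata",
    "poststratify",
    "empirical_strata",
]

# Default band edges: a band covers [edge[i], edge[i+1]) labelled "lo-hi".
DEFAULT_AGE_EDGES = (17, 27, 37, 47, 57, 67, 200)
DEFAULT_EDUCATION_EDGES = (0, 5, 10, 15, 20, 25, 31)
DEFAULT_CHILDREN_EDGES = (0, 1, 3, 5, 100)

BAND_COLUMNS = {
    "age_band": ("age", DEFAULT_AGE_EDGES),
    "education_band": ("education", DEFAULT_EDUCATION_EDGES),
    "children_band": ("children", DEFAULT_CHILDREN_EDGES),
}
PLAIN_COLUMNS = ("sex", "food_insecure")
TARGET_LABEL = "poststratified"


def band_label(value, edges: Sequence[int]) -> str:
    """Label of the half-open band [edge, next) containing ``value``."""
    v = float(value)
    for lo, hi in zip(edges[:-1], edges[1:]):
        if lo <= v < hi:
            return f"{lo}-{hi - 1}"
    raise ModelError(f"value {value!r} outside band edges {tuple(edges)}")


@dataclass
class StrataTable:
    """Weighted covariate strata for a target population.

    ``frame`` holds one row per stratum: any subset of the columns
    {sex, age_band, education_band, children_band, food_insecure}
    plus a nonnegative ``weight`` column.  Weights are normalized to sum
    to one on construction.
    """

    frame: pd.DataFrame
    band_edges: dict = None

    def __post_init__(self) -> None:
        if "weight" not in self.frame.columns:
            raise ModelError("strata table needs a 'weight' column")
        known = set(BAND_COLUMNS) | set(PLAIN_COLUMNS) | {"weight"}
        unknown = set(self.frame.columns) - known
        if unknown:
            raise ModelError(f"unknown strata column(s): {sorted(unknown)}")
        w = self.frame["weight"].to_numpy(dtype=float)
        if np.any(w < 0) or not np.isfinite(w).all():
            raise ModelError("strata weights must be finite and nonnegative")
        total = w.sum()
        if total <= 0:
            raise ModelError("strata weights must not all be zero")
        frame = self.frame.copy().reset_index(drop=True)
        frame["weight"] = w / total
        dup_cols = [c for c in frame.columns if c != "weight"]
        if dup_cols and frame.duplicated(subset=dup_cols).any():
            raise ModelError("strata definitions are not disjoint")
        self.frame = frame
        if self.band_edges is None:
            self.band_edges = {
                name: edges for name, (_, edges) in BAND_COLUMNS.items()
            }

    @property
    def covariate_columns(self) -> list:
        return [c for c in self.frame.columns if c != "weight"]

    @property
    def weights(self) -> np.ndarray:
        return self.frame["weight"].to_numpy(dtype=float)

    @classmethod
    def from_csv(cls, path, band_edges: Optional[dict] = None
                 ) -> "StrataTable":
        frame = pd.read_csv(path, comment="#", dtype={"sex": "Int64",
                                                      "food_insecure": "Int64"})
        return cls(frame, band_edges=band_edges)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False, lineterminator="\n")


def _row_keys(table: pd.DataFrame, strata: StrataTable) -> pd.DataFrame:
    """Banded covariate labels for every individual, matching strata columns."""
    keys = {}
    for col in strata.covariate_columns:
        if col in PLAIN_COLUMNS:
            keys[col] = table[col].to_numpy(dtype=np.int64)
        else:
            source, _ = BAND_COLUMNS[col]
            edges = strata.band_edges[col]
            keys[col] = [
                band_label(v, edges) for v in table[source].to_numpy()
            ]
    return pd.DataFrame(keys, index=range(len(table)))


def assign_strata(table: pd.DataFrame, strata: StrataTable) -> np.ndarray:
    """Map each individual to the index of its unique stratum.

    Raises with a list of offending rows if any individual matches zero
    strata (the definitions fail to cover) or more than one (not
    disjoint).
    """
    keys = _row_keys(table, strata)
    cols = strata.covariate_columns
    if not cols:
        return np.zeros(len(table), dtype=np.int64)
    lookup: dict = {}
    for si, srow in strata.frame[cols].iterrows():
        key = tuple(srow[c] for c in cols)
        if key in lookup:
            raise ModelError(f"strata rows {lookup[key]} and {si} coincide")
        lookup[key] = si
    assignment = np.empty(len(table), dtype=np.int64)
    unmatched = []
    for i in range(len(table)):
        key = tuple(keys.iloc[i][c] for c in cols)
        si = lookup.get(key)
        if si is None:
            unmatched.append(i)
        else:
            assignment[i] = si
    if unmatched:
        raise ModelError(
            f"{len(unmatched)} individual(s) match no stratum "
            f"(first few row indices: {unmatched[:5]})"
        )
    return assignment


def empirical_strata(table: pd.DataFrame,
                     columns: Sequence[str] = ("sex", "age_band",
                                               "education_band"),
                     band_edges: Optional[dict] = None) -> StrataTable:
    """Build a strata table whose weights are the sample's own frequencies."""
    edges = band_edges or {
        name: e for name, (_, e) in BAND_COLUMNS.items()
    }
    keys = {}
    for col in columns:
        if col in PLAIN_COLUMNS:
            keys[col] = table[col].to_numpy(dtype=np.int64)
        else:
            source, default_edges = BAND_COLUMNS[col]
            keys[col] = [
                band_label(v, edges.get(col, default_edges))
                for v in table[source].to_numpy()
            ]
    kf = pd.DataFrame(keys)
    counts = kf.value_counts().reset_index(name="weight")
    counts["weight"] = counts["weight"] / counts["weight"].sum()
    return StrataTable(counts, band_edges=edges)


def poststratify(
    potential: np.ndarray,
    strata: StrataTable,
    table: pd.DataFrame,
    grid: ExposureGrid,
    *,
    interval: float = 0.95,
) -> CounterfactualSummary:
    """Weight within-stratum mean probability vectors by target weights.

    Per draw and exposure level the output is
    ``sum_g w_g * mean_{i in g} p_i`` — identical to plain marginalization
    when the weights equal the empirical stratum frequencies.  Strata
    carrying positive weight but containing no sampled individuals are an
    error (nothing to predict from).
    """
    m, n, L, K = potential.shape
    if len(table) != n:
        raise ModelError("table row count does not match potential outcomes")
    assignment = assign_strata(table, strata)
    weights = strata.weights
    present = np.bincount(assignment, minlength=len(weights)) > 0
    bad = np.flatnonzero((weights > 0) & ~present)
    if bad.size:
        raise ModelError(
            f"stratum(ux) {bad.tolist()} have positive weight but no "
            "sampled individuals"
        )
    combined = np.zeros((m, L, K))
    for g in np.flatnonzero(present):
        idx = np.flatnonzero(assignment == g)
        combined += weights[g] * potential[:, idx].mean(axis=1)
    mean = combined.mean(axis=0)
    lower, upper = _interval_bounds(combined, interval)
    rows = []
    for li, level in enumerate(grid.levels):
        for k in range(K):
            rows.append({
                "unit": TARGET_LABEL,
                "exposure": grid.exposure,
                "level": level,
                "category": k + 1,
                "mean": mean[li, k],
                "lower": lower[li, k],
                "upper": upper[li, k],
            })
    return CounterfactualSummary(
        table=pd.DataFrame(rows), interval=interval, exposure=grid.exposure,
    )
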