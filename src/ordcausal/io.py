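"""Survey table I/O: schema validation, missingness accounting and
complete-case filtering.

Rows with out-of-range values are flagged with a reason, never silently
dropped; downstream stages decide what to do with them.  All counts are
kept so a pipeline run can reconcile input = used + dropped + invalid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .simulate import SCHEMA_COLUMNS

__all__ = [
    "SchemaError",
    "SurveyReadResult",
    "read_survey_csv",
    "write_survey_csv",
    "complete_cases",
    "SCHEMA_COLUMNS",
]

log = logging.getLogger("ordcausal")

# (lower, upper) inclusive bounds; None = unbounded
_RANGES = {
    "sex": (0, 1),
    "age": (17, None),
    "education": (0, 30),
    "children": (0, None),
    "food_insecure": (0, 1),
    "think_freq": (1, 5),
    "ritual_freq": (1, 5),
}
_NUMERIC_COLUMNS = tuple(_RANGES)


class SchemaError(ValueError):
    pass


@dataclass
class SurveyReadResult:
    """A parsed survey table plus its validation report."""

    table: pd.DataFrame                 # all rows, with a boolean 'valid'
    missingness: pd.Series              # per-column missing-cell counts
    invalid: pd.DataFrame               # columns: row, reason
    n_rows: int

    @property
    def valid_table(self) -> pd.DataFrame:
        return (
            self.table[self.table["_row_valid"]]
            .drop(columns="_row_valid")
            .reset_index(drop=True)
        )

    @property
    def n_invalid(self) -> int:
        return int((~self.table["_row_valid"]).sum())


def read_survey_csv(path, required: Sequence[str] = SCHEMA_COLUMNS
                    ) -> SurveyReadResult:
    """Parse and validate a survey CSV.

    Empty cells become missing values and are counted per column; cells
    violating the schema ranges (ordinal outcomes 1-5, indicators 0/1,
    education 0-30, age >= 17, children >= 0) or that are non-numeric
    flag the whole row with a reason.
    """
    try:
        raw = pd.read_csv(path, dtype=str, comment="#",
                          skip_blank_lines=True)
    except (OSError, pd.errors.ParserError) as exc:
        raise SchemaError(f"cannot parse {path}: {exc}") from exc
    missing_cols = [c for c in required if c not in raw.columns]
    if missing_cols:
        raise SchemaError(f"missing required column(s): {missing_cols}")

    table = pd.DataFrame({"site": raw["site"].astype("string")})
    reasons: list[tuple[int, str]] = []
    valid = np.ones(len(raw), dtype=bool)
    for col in _NUMERIC_COLUMNS:
        if col not in raw.columns:
            continue
        text = raw[col].astype("string").str.strip()
        blank = text.isna() | (text == "")
        values = pd.to_numeric(text.where(~blank), errors="coerce")
        unparseable = values.isna() & ~blank
        lo, hi = _RANGES[col]
        out_of_range = pd.Series(False, index=values.index)
        if lo is not None:
            out_of_range |= values < lo
        if hi is not None:
            out_of_range |= values > hi
        non_integer = values.notna() & (values != np.floor(values))
        for i in np.flatnonzero(unparseable):
            reasons.append((i, f"{col}: unparseable value {text.iloc[i]!r}"))
        for i in np.flatnonzero(out_of_range.fillna(False)):
            reasons.append((i, f"{col}: value {values.iloc[i]:g} out of range"))
        for i in np.flatnonzero(non_integer & ~out_of_range.fillna(False)):
            reasons.append((i, f"{col}: non-integer value {values.iloc[i]:g}"))
        bad = unparseable | out_of_range.fillna(False) | non_integer
        valid &= ~bad.to_numpy()
        table[col] = values
    site_blank = table["site"].isna() | (table["site"].str.strip() == "")
    table.loc[site_blank, "site"] = pd.NA

    missingness = table.isna().sum()
    table["_row_valid"] = valid
    invalid = pd.DataFrame(reasons, columns=["row", "reason"])
    if len(invalid):
        log.warning("flagged %d invalid row(s) in %s", invalid["row"].nunique(),
                    path)
    return SurveyReadResult(
        table=table, missingness=missingness, invalid=invalid,
        n_rows=len(table),
    )


def write_survey_csv(table: pd.DataFrame, path) -> None:
    """Write the public schema columns; missing cells become empty strings.

    Private (underscore-prefixed) generator columns are dropped.
    """
    cols = [c for c in SCHEMA_COLUMNS if c in table.columns]
    out = table[cols].copy()
    for col in out.columns:
        if col == "site":
            continue
        as_float = pd.to_numeric(out[col])
        out[col] = as_float.map(
            lambda v: "" if pd.isna(v) else str(int(v))
        )
    out.to_csv(path, index=False, lineterminator="\n")


def complete_cases(table: pd.DataFrame,
                   variables: Sequence[str]) -> pd.DataFrame:
    """Rows with no missing value among ``variables``; logs per-site counts."""
    unknown = [v for v in variables if v not in table.columns]
    if unknown:
        raise SchemaError(f"unknown variable(s): {unknown}")
    keep = table[list(variables)].notna().all(axis=1)
    kept = table[keep].reset_index(drop=True)
    if "site" in table.columns:
        for site, group in table.groupby("site", dropna=False):
            retained = int(keep[group.index].sum())
            log.info(
                "complete cases at %s: retained %d / %d",
                site, retained, len(group),
            )
    log.info("complete cases overall: retained %d / %d", len(kept), len(table))
    return kept
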