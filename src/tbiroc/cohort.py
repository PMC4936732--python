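"""Cohort containers, delimited-text IO, complete-case filtering and
frequency summaries.

A :class:`RawCohort` may contain missing-data codes ("no data", "scan not
done", ...); a :class:`Cohort` is the complete-case view with none.  The
complete-case rule excludes a record if *any* of the predictors or the
outcome carries a missing code — the analysis performs no imputation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .schema import Schema, alias_map, POOR_OUTCOME

__all__ = [
    "RawCohort",
    "Cohort",
    "ExclusionReport",
    "read_cohort",
    "write_cohort",
    "complete_case_filter",
    "summarize",
]


@dataclass
class RawCohort:
    """Patient-level categorical records; values may be missing codes."""

    records: pd.DataFrame
    schema: Schema

    def __post_init__(self) -> None:
        self.validate()

    @property
    def n(self) -> int:
        return len(self.records)

    def validate(self) -> None:
        for name in self.schema.names:
            if name not in self.records.columns:
                raise ValueError(f"missing required column: {name!r}")
            allowed = set(self.schema[name].all_labels)
            bad = ~self.records[name].isin(allowed)
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise ValueError(
                    f"unrecognized label {self.records[name].iloc[row]!r} "
                    f"for variable {name!r} at row {row}"
                )


@dataclass
class Cohort(RawCohort):
    """Complete-case cohort: no missing codes in predictors or outcome."""

    def validate(self) -> None:
        super().validate()
        for name in self.schema.names:
            codes = set(self.schema[name].missing_codes)
            if codes and self.records[name].isin(codes).any():
                raise ValueError(f"complete-case cohort contains missing code in {name!r}")

    @property
    def y(self) -> np.ndarray:
        """Binary outcome vector; 1 = poor outcome (death or severe disability)."""
        out = self.schema.outcome
        if out is None:
            raise ValueError("schema has no outcome variable")
        positive = self.schema[out].categories[0]
        return (self.records[out] == positive).to_numpy(dtype=int)


@dataclass
class ExclusionReport:
    """Bookkeeping of complete-case exclusions; retained + excluded = input n."""

    n_input: int
    n_retained: int
    per_code: pd.DataFrame  # columns: variable, code, n_records

    @property
    def n_excluded(self) -> int:
        return self.n_input - self.n_retained

    def to_json(self, path: str | Path) -> None:
        obj = {
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "n_excluded": self.n_excluded,
            "per_code": self.per_code.to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(obj, indent=2))

    def to_csv(self, path: str | Path) -> None:
        self.per_code.to_csv(path, index=False)


def read_cohort(path: str | Path, schema: Schema) -> RawCohort:
    """Read a comma-separated cohort file, validating every cell.

    The header must name every schema variable.  Labels are matched
    exactly first, then through a tolerant alias map (case-insensitive,
    underscores for spaces); anything else is rejected with its row
    number and variable name.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [n for n in schema.names if n not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {missing}")
    aliases = alias_map(schema)
    for name in schema.names:
        col = df[name].str.strip()
        exact = set(schema[name].all_labels)
        amap = aliases[name]
        canon = col.str.lower().str.replace("_", " ", regex=False)
        mapped = col.where(col.isin(exact), canon.map(amap))
        bad = mapped.isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"unrecognized category label {df[name].iloc[row]!r} for "
                f"variable {name!r} at row {row}"
            )
        df[name] = mapped
    return RawCohort(df[list(schema.names)].reset_index(drop=True), schema)


def write_cohort(cohort: RawCohort, path: str | Path) -> None:
    """Write a cohort as UTF-8 CSV with exact category labels."""
    cohort.records.to_csv(path, index=False)


def complete_case_filter(raw: RawCohort) -> tuple[Cohort, ExclusionReport]:
    """Drop every record with a missing code in any predictor or the outcome.

    The report counts, per (variable, code), how many records carried that
    code; a record missing several variables is counted under each, so the
    per-code column sums can exceed the number of excluded records.
    """
    df = raw.records
    drop = np.zeros(len(df), dtype=bool)
    rows = []
    for v in raw.schema:
        for code in v.missing_codes:
            hit = (df[v.name] == code).to_numpy()
            if hit.any():
                rows.append({"variable": v.name, "code": code, "n_records": int(hit.sum())})
            drop |= hit
    per_code = pd.DataFrame(rows, columns=["variable", "code", "n_records"])
    kept = df.loc[~drop].reset_index(drop=True)
    report = ExclusionReport(n_input=len(df), n_retained=len(kept), per_code=per_code)
    return Cohort(kept, raw.schema), report


def _round_half_up(x: np.ndarray, decimals: int = 2) -> np.ndarray:
    factor = 10.0 ** decimals
    return np.floor(x * factor + 0.5) / factor


def summarize(cohort: RawCohort, include_missing: bool = True) -> pd.DataFrame:
    """Per variable x category counts and percentages over the cohort size.

    Percentages are reported to two decimals with half-up rounding.  Rows
    appear in schema order (categories first, then missing codes when
    ``include_missing``); categories with zero count are retained.
    """
    df = cohort.records
    n = len(df)
    rows = []
    for v in cohort.schema:
        labels = v.all_labels if include_missing else v.categories
        counts = df[v.name].value_counts()
        for lbl in labels:
            c = int(counts.get(lbl, 0))
            pct = float(_round_half_up(np.array(100.0 * c / n))) if n else 0.0
            rows.append({"variable": v.name, "group": v.group,
                         "category": lbl, "count": c, "percent": pct})
    return pd.DataFrame(rows)


def summarize_panels(raw: RawCohort) -> pd.DataFrame:
    """Three-panel layout: complete cases only, incomplete only, entire cohort."""
    complete, _ = complete_case_filter(raw)
    drop = np.zeros(raw.n, dtype=bool)
    for v in raw.schema:
        for code in v.missing_codes:
            drop |= (raw.records[v.name] == code).to_numpy()
    missing_only = RawCohort(raw.records.loc[drop].reset_index(drop=True), raw.schema)
    panels = {
        "complete": summarize(complete, include_missing=False),
        "missing": summarize(missing_only),
        "entire": summarize(raw),
    }
    frames = []
    for key, tbl in panels.items():
        t = tbl.rename(columns={"count": f"count_{key}", "percent": f"percent_{key}"})
        frames.append(t.set_index(["variable", "category"])[[f"count_{key}", f"percent_{key}"]])
    merged = pd.concat(frames, axis=1).reset_index()
    groups = {v.name: v.group for v in raw.schema}
    merged.insert(1, "group", merged["variable"].map(groups))
    return merged
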