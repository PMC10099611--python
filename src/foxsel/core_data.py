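"""Data model and I/O for the hierarchical N-addition field design.

The study layout is a set of replicated plots, each split into one *ambient*
and one *addition* (fertilized) subplot.  Three tabular inputs are handled:

* individual-level records of a focal annual plant (traits, fruit count,
  herbivory and exclusion flags),
* subplot-level species biomass harvests, and
* photosynthetically-active-radiation (PAR) readings by canopy height.

All tables travel as :class:`pandas.DataFrame` objects with fixed column
names; reading functions validate row-level invariants and report offending
rows rather than silently coercing them.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

TREATMENTS = ("ambient", "addition")
TRAITS = ("height", "leaf_count", "sla", "flowering_day")

SEEDLING_CLASSES = (">10cm", ">5-10cm", "2-5cm", "<2cm")

#: canonical individual-table columns (in write order)
INDIVIDUAL_COLUMNS = (
    "plot_id",
    "subplot_id",
    "treatment",
    "seedling_class",
    "height",
    "leaf_count",
    "sla",
    "flowering_day",
    "fruit_count",
    "main_panicle_length",
    "herbivory",
    "fitness_excluded",
)

REQUIRED_INDIVIDUAL_COLUMNS = (
    "plot_id",
    "subplot_id",
    "treatment",
    "height",
    "leaf_count",
    "sla",
    "flowering_day",
    "fruit_count",
    "herbivory",
    "fitness_excluded",
)

COMMUNITY_COLUMNS = ("subplot_id", "species", "biomass", "harvest_area")
PAR_COLUMNS = ("subplot_id", "height", "par")

_NA_VALUES = ["", "NA", "NaN", "nan"]

_TRUE = {"true", "t", "1", "yes", "y", "1.0"}
_FALSE = {"false", "f", "0", "no", "n", "0.0"}


class DataError(Exception):
    """Base class for data-layer failures."""


class SchemaError(DataError):
    """A required column is missing from the input."""


class ParseError(DataError):
    """A cell could not be parsed to its declared type."""


class DesignError(DataError):
    """Records are inconsistent with the declared study design."""


class InsufficientDataError(DataError):
    """Too few observations for the requested quantity."""


@dataclass
class RowIssue:
    row: int
    column: str
    message: str

    def as_dict(self) -> dict:
        return {"row": self.row, "column": self.column, "message": self.message}


@dataclass
class ValidationReport:
    """Row-indexed account of what a reader accepted and rejected."""

    table: str
    n_input: int
    n_valid: int
    rejected: list[RowIssue] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "table": self.table,
                "n_input": self.n_input,
                "n_valid": self.n_valid,
                "rejected": [r.as_dict() for r in self.rejected],
            },
            indent=2,
            sort_keys=True,
        )


@dataclass(frozen=True)
class StudyDesign:
    """Plot -> (ambient subplot, addition subplot) mapping.

    Every plot carries exactly one subplot per treatment; record triples
    (plot, subplot, treatment) must be consistent with this map.
    """

    subplot_map: Mapping[str, Mapping[str, str]]

    def __post_init__(self):
        for plot, sub in self.subplot_map.items():
            if set(sub) != set(TREATMENTS):
                raise DesignError(
                    f"plot {plot!r} must map exactly one subplot per treatment, got {sorted(sub)}"
                )

    @property
    def plots(self) -> tuple[str, ...]:
        return tuple(self.subplot_map)

    @property
    def subplots(self) -> tuple[str, ...]:
        return tuple(
            self.subplot_map[p][t] for p in self.subplot_map for t in TREATMENTS
        )

    def subplot_treatment(self) -> dict[str, str]:
        return {
            self.subplot_map[p][t]: t for p in self.subplot_map for t in TREATMENTS
        }

    def subplot_plot(self) -> dict[str, str]:
        return {
            self.subplot_map[p][t]: p for p in self.subplot_map for t in TREATMENTS
        }

    @classmethod
    def from_records(cls, records: pd.DataFrame) -> "StudyDesign":
        """Infer the design from consistent record triples."""
        triples = records[["plot_id", "subplot_id", "treatment"]].drop_duplicates()
        mapping: dict[str, dict[str, str]] = {}
        for plot, subplot, trt in triples.itertuples(index=False):
            mapping.setdefault(plot, {})
            if trt in mapping[plot] and mapping[plot][trt] != subplot:
                raise DesignError(
                    f"plot {plot!r} has two {trt} subplots: "
                    f"{mapping[plot][trt]!r}, {subplot!r}"
                )
            mapping[plot][trt] = subplot
        return cls({p: dict(sub) for p, sub in mapping.items()})


@dataclass
class DesignSummary:
    total: int
    per_subplot: pd.DataFrame  # subplot_id, plot_id, treatment, n
    per_treatment: dict[str, int]
    low_n_subplots: list[str]


def _parse_bool(series: pd.Series, column: str, issues: list[RowIssue]) -> pd.Series:
    out = pd.Series(False, index=series.index, dtype=bool)
    for idx, val in series.items():
        if isinstance(val, (bool, np.bool_)):
            out[idx] = bool(val)
            continue
        if pd.isna(val):
            out[idx] = False
            continue
        s = str(val).strip().lower()
        if s in _TRUE:
            out[idx] = True
        elif s in _FALSE:
            out[idx] = False
        else:
            raise ParseError(f"row {idx}: column {column!r}: not a boolean: {val!r}")
    return out


def _read_table(source, delimiter: str | None) -> pd.DataFrame:
    kwargs = dict(na_values=_NA_VALUES, keep_default_na=False, skipinitialspace=True)
    if delimiter is None:
        return pd.read_csv(source, sep=None, engine="python", **kwargs)
    return pd.read_csv(source, sep=delimiter, **kwargs)


def _to_numeric(df: pd.DataFrame, column: str) -> pd.Series:
    raw = df[column]
    num = pd.to_numeric(raw, errors="coerce")
    bad = num.isna() & raw.notna()
    if bad.any():
        rows = ", ".join(str(i) for i in df.index[bad][:10])
        raise ParseError(f"column {column!r}: non-numeric value(s) at row(s) {rows}")
    return num


def read_individuals(
    source,
    *,
    delimiter: str | None = None,
    column_map: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, ValidationReport]:
    """Read and validate an individual-level table.

    Parameters
    ----------
    source
        Path or text handle of a delimited file (delimiter sniffed unless
        given).  Missing values may be empty fields or ``NA``.
    column_map
        Optional mapping from canonical column name to the file's header
        name, for files with bespoke headers.

    Returns the validated frame (rows violating invariants dropped) and a
    :class:`ValidationReport` listing each rejected row.
    """
    df = _read_table(source, delimiter)
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    missing = [c for c in REQUIRED_INDIVIDUAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")
    for opt in ("seedling_class", "main_panicle_length"):
        if opt not in df.columns:
            df[opt] = np.nan
    df = df.reset_index(drop=True)

    issues: list[RowIssue] = []
    for col in ("height", "leaf_count", "sla", "flowering_day", "fruit_count",
                "main_panicle_length"):
        df[col] = _to_numeric(df, col)
    df["herbivory"] = _parse_bool(df["herbivory"], "herbivory", issues)
    df["fitness_excluded"] = _parse_bool(df["fitness_excluded"], "fitness_excluded", issues)
    for col in ("plot_id", "subplot_id", "treatment", "seedling_class"):
        df[col] = df[col].astype("string").str.strip()

    bad = pd.Series(False, index=df.index)

    def _flag(mask: pd.Series, column: str, message: str) -> None:
        for idx in df.index[mask & ~bad]:
            issues.append(RowIssue(int(idx), column, message))
        bad.loc[mask] = True

    _flag(~df["treatment"].isin(TREATMENTS), "treatment",
          f"treatment must be one of {TREATMENTS}")
    _flag(df["fruit_count"].notna() & (df["fruit_count"] < 0), "fruit_count",
          "fruit_count must be >= 0")
    _flag(df["sla"].notna() & (df["sla"] <= 0), "sla", "sla must be > 0")
    _flag(df["leaf_count"].notna() & (df["leaf_count"] < 0), "leaf_count",
          "leaf_count must be >= 0")
    _flag(df["seedling_class"].notna() & ~df["seedling_class"].isin(SEEDLING_CLASSES),
          "seedling_class", f"seedling_class must be one of {SEEDLING_CLASSES}")

    valid = df.loc[~bad, list(INDIVIDUAL_COLUMNS)].reset_index(drop=True)
    report = ValidationReport("individuals", len(df), len(valid), issues)
    return valid, report


def write_individuals(df: pd.DataFrame, target) -> None:
    """Write a canonical individual CSV (missing values as empty fields)."""
    out = df.copy()
    out["herbivory"] = out["herbivory"].map({True: "true", False: "false"})
    out["fitness_excluded"] = out["fitness_excluded"].map({True: "true", False: "false"})
    out[list(INDIVIDUAL_COLUMNS)].to_csv(target, index=False, na_rep="")


def read_community(
    source, *, delimiter: str | None = None
) -> tuple[pd.DataFrame, ValidationReport]:
    """Read the per-(subplot, species) biomass table."""
    df = _read_table(source, delimiter)
    missing = [c for c in COMMUNITY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")
    df = df.reset_index(drop=True)
    for col in ("biomass", "harvest_area"):
        df[col] = _to_numeric(df, col)
    issues: list[RowIssue] = []
    bad = pd.Series(False, index=df.index)
    for mask, col, msg in (
        (df["biomass"].isna() | (df["biomass"] < 0), "biomass", "biomass must be >= 0"),
        (df["harvest_area"].isna() | (df["harvest_area"] <= 0), "harvest_area",
         "harvest_area must be > 0"),
    ):
        for idx in df.index[mask & ~bad]:
            issues.append(RowIssue(int(idx), col, msg))
        bad |= mask
    dup = df.duplicated(subset=["subplot_id", "species"], keep="first")
    for idx in df.index[dup & ~bad]:
        issues.append(RowIssue(int(idx), "species", "(subplot, species) must be unique"))
    bad |= dup
    valid = df.loc[~bad, list(COMMUNITY_COLUMNS)].reset_index(drop=True)
    return valid, ValidationReport("community", len(df), len(valid), issues)


def read_par(
    source, *, delimiter: str | None = None
) -> tuple[pd.DataFrame, ValidationReport]:
    """Read the PAR-by-height table (PAR must be positive: logs are taken)."""
    df = _read_table(source, delimiter)
    missing = [c for c in PAR_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")
    df = df.reset_index(drop=True)
    for col in ("height", "par"):
        df[col] = _to_numeric(df, col)
    issues: list[RowIssue] = []
    bad = df["par"].isna() | (df["par"] <= 0) | df["height"].isna()
    for idx in df.index[bad]:
        issues.append(RowIssue(int(idx), "par", "par must be > 0 and height present"))
    valid = df.loc[~bad, list(PAR_COLUMNS)].reset_index(drop=True)
    return valid, ValidationReport("par", len(df), len(valid), issues)


def validate_design(
    records: pd.DataFrame, design: StudyDesign, *, min_n: int = 1
) -> DesignSummary:
    """Check records against the design; count individuals per subplot.

    Raises :class:`DesignError` if a record references a subplot absent from
    the design or carries an inconsistent (plot, treatment) pair for its
    subplot.  Subplots with fewer than ``min_n`` records are flagged.
    """
    sub_trt = design.subplot_treatment()
    sub_plot = design.subplot_plot()
    unknown = sorted(set(records["subplot_id"]) - set(sub_trt))
    if unknown:
        raise DesignError(f"subplot(s) not in design: {unknown}")
    for sub, trt, plot in (
        records[["subplot_id", "treatment", "plot_id"]].drop_duplicates().itertuples(index=False)
    ):
        if sub_trt[sub] != trt:
            raise DesignError(
                f"subplot {sub!r} is {sub_trt[sub]} in the design but {trt} in records"
            )
        if sub_plot[sub] != plot:
            raise DesignError(
                f"subplot {sub!r} belongs to plot {sub_plot[sub]!r} in the design, "
                f"not {plot!r}"
            )
    rows = []
    counts = records.groupby("subplot_id").size()
    for sub in design.subplots:
        rows.append(
            {
                "subplot_id": sub,
                "plot_id": sub_plot[sub],
                "treatment": sub_trt[sub],
                "n": int(counts.get(sub, 0)),
            }
        )
    per_subplot = pd.DataFrame(rows)
    per_treatment = {
        t: int(per_subplot.loc[per_subplot["treatment"] == t, "n"].sum())
        for t in TREATMENTS
    }
    low = per_subplot.loc[per_subplot["n"] < min_n, "subplot_id"].tolist()
    return DesignSummary(int(len(records)), per_subplot, per_treatment, low)


def apply_fitness_exclusions(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition records into (fitness-analysis set, trait-only set).

    The trait-only set is the full input; the fitness set drops rows flagged
    ``fitness_excluded``.  The two sets always partition exactly: the fitness
    set plus the flagged rows equals the input.
    """
    fitness = records.loc[~records["fitness_excluded"]].copy()
    traits = records.copy()
    return fitness, traits


def survival(records: pd.DataFrame) -> pd.Series:
    """Survival to fruit production, derived as ``fruit_count > 0``.

    Missing fruit counts (fitness-excluded individuals) stay missing.
    """
    w = records["fruit_count"]
    out = (w > 0).astype(float)
    out[w.isna()] = np.nan
    return out


def panicle_qc(records: pd.DataFrame) -> tuple[float, float, int]:
    """Pearson correlation between fruit count and main panicle length.

    A fruit-collection quality check: fruit counts should track panicle
    length among individuals measured for both.  Returns ``(r, p, n)``.
    """
    sub = records[["fruit_count", "main_panicle_length"]].dropna()
    if len(sub) < 3:
        raise InsufficientDataError(
            f"need >= 3 complete (fruit, panicle) pairs, have {len(sub)}"
        )
    x = sub["fruit_count"].to_numpy(float)
    y = sub["main_panicle_length"].to_numpy(float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise InsufficientDataError("zero variance: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), int(len(sub))
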