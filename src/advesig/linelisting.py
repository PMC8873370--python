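"""Reading, de-duplication and filtering of spontaneous-report line listings.

A *line listing* is the one-row-per-(report, reaction) export format used by
pharmacovigilance dashboards: each row carries one suspect drug, one reaction
preferred term (PT) with its system organ class (SOC), coarse demographics and
administrative fields.  A report with several PTs spans several rows sharing a
``report_id``; PT-level tallies count rows, report-level counting uses
``report_id``.

The in-memory container is a :class:`pandas.DataFrame` with the columns of
:data:`SCHEMA_COLUMNS`; :class:`Report` is the row-level record type used for
programmatic construction and round-tripping.

Text fields are compared case-insensitively after whitespace trimming; the
reader strips whitespace on ingest and comparisons (de-duplication, filtering)
casefold internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import DataError, SchemaError

#: Documented CSV schema, in column order.
SCHEMA_COLUMNS = [
    "report_id",
    "drug",
    "reaction_pt",
    "soc",
    "age_group",
    "sex",
    "route",
    "year",
    "serious",
    "outcome",
    "concomitant",
]

#: Columns that must be present (``outcome``/``concomitant`` may be absent).
MANDATORY_COLUMNS = SCHEMA_COLUMNS[:9]

#: Default de-duplication key.  The dashboards' manual duplicate review is not
#: reproducible, so a deterministic surrogate key over payload fields is used;
#: two rows agreeing on every key field are treated as the same case.
DEFAULT_DEDUP_KEY = (
    "drug",
    "reaction_pt",
    "age_group",
    "sex",
    "route",
    "year",
    "serious",
)

_TEXT_COLUMNS = [
    "report_id",
    "drug",
    "reaction_pt",
    "soc",
    "age_group",
    "sex",
    "route",
    "outcome",
    "concomitant",
]

_TRUE_STRINGS = {"true", "1", "yes", "y", "t"}
_FALSE_STRINGS = {"false", "0", "no", "n", "f", ""}


@dataclass(frozen=True)
class Report:
    """One (report, reaction) row of a line listing."""

    report_id: str
    drug: str
    reaction_pt: str
    soc: str
    age_group: str
    sex: str
    route: str
    year: int
    serious: bool
    outcome: str = ""
    concomitant: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.report_id:
            raise DataError("report_id must be non-empty")

    def to_row(self) -> dict:
        row = {c: getattr(self, c) for c in SCHEMA_COLUMNS[:10]}
        row["concomitant"] = ";".join(self.concomitant)
        return row


@dataclass(frozen=True)
class RowError:
    """A malformed data row, reported with its 1-based file line number."""

    line: int
    column: str
    value: str
    message: str


@dataclass(frozen=True)
class FilterSpec:
    """Inclusion criteria for building an analysis set.

    ``None`` for a categorical criterion means "keep all".  Year bounds are
    inclusive on both ends.
    """

    age_groups: frozenset[str] | None = None
    sexes: frozenset[str] | None = None
    routes: frozenset[str] | None = None
    years: tuple[int, int] | None = None
    socs: frozenset[str] | None = None
    pts: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if self.years is not None and self.years[0] > self.years[1]:
            raise DataError(f"year range start {self.years[0]} > end {self.years[1]}")
        for name in ("age_groups", "sexes", "routes", "socs", "pts"):
            value = getattr(self, name)
            if value is not None and not isinstance(value, frozenset):
                object.__setattr__(self, name, frozenset(value))


@dataclass
class AnalysisSet:
    """Filtered line listing plus the provenance of how it was produced."""

    reports: pd.DataFrame
    spec: FilterSpec | None = None
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.reports)


@dataclass
class ReadResult:
    """Parsed rows plus the row errors collected along the way."""

    reports: pd.DataFrame
    errors: list[RowError]


def _norm(series: pd.Series) -> pd.Series:
    return series.astype(str).str.strip().str.casefold()


def reports_to_frame(reports: Iterable[Report]) -> pd.DataFrame:
    """Build a schema DataFrame from :class:`Report` records."""
    rows = [r.to_row() for r in reports]
    if not rows:
        return pd.DataFrame(columns=SCHEMA_COLUMNS)
    return pd.DataFrame(rows, columns=SCHEMA_COLUMNS)


def frame_to_reports(df: pd.DataFrame) -> list[Report]:
    """Inverse of :func:`reports_to_frame`."""
    out = []
    for row in df.itertuples(index=False):
        conc = getattr(row, "concomitant", "") or ""
        out.append(
            Report(
                report_id=str(row.report_id),
                drug=str(row.drug),
                reaction_pt=str(row.reaction_pt),
                soc=str(row.soc),
                age_group=str(row.age_group),
                sex=str(row.sex),
                route=str(row.route),
                year=int(row.year),
                serious=bool(row.serious),
                outcome=str(getattr(row, "outcome", "") or ""),
                concomitant=tuple(p for p in str(conc).split(";") if p),
            )
        )
    return out


def read_line_listing(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    *,
    strict: bool = False,
) -> ReadResult:
    """Read a CSV line listing into the schema DataFrame.

    Parameters
    ----------
    path
        CSV file with a header row.
    schema
        Optional mapping from *file* column names to schema column names, to
        accommodate real dashboard exports whose headers differ.
    strict
        If True, the first malformed row raises :class:`DataError`; otherwise
        malformed rows are dropped and reported in ``errors`` with their
        1-based file line numbers.

    Unknown columns are preserved in the returned frame (passthrough payload).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if schema:
        df = df.rename(columns=dict(schema))
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s): {', '.join(missing)}")
    for col in ("outcome", "concomitant"):
        if col not in df.columns:
            df[col] = ""
    for col in _TEXT_COLUMNS:
        df[col] = df[col].astype(str).str.strip()

    errors: list[RowError] = []
    # line number = positional row index + 2 (1-based, plus header line)
    year_num = pd.to_numeric(df["year"].str.strip(), errors="coerce")
    bad_year = year_num.isna()
    serious_norm = df["serious"].str.strip().str.casefold()
    bad_serious = ~serious_norm.isin(_TRUE_STRINGS | _FALSE_STRINGS)
    bad_id = df["report_id"] == ""
    for pos in df.index[bad_year | bad_serious | bad_id]:
        line = int(df.index.get_loc(pos)) + 2
        if bad_id.loc[pos]:
            errors.append(RowError(line, "report_id", "", "empty report_id"))
        elif bad_year.loc[pos]:
            errors.append(
                RowError(line, "year", df.loc[pos, "year"], "unparseable year")
            )
        else:
            errors.append(
                RowError(
                    line, "serious", df.loc[pos, "serious"], "unparseable boolean"
                )
            )
    if errors and strict:
        first = errors[0]
        raise DataError(
            f"{path}:{first.line}: {first.message} ({first.column}={first.value!r})"
        )
    keep = ~(bad_year | bad_serious | bad_id)
    df = df.loc[keep].copy()
    df["year"] = year_num[keep].astype(int)
    df["serious"] = serious_norm[keep].isin(_TRUE_STRINGS)
    ordered = [c for c in SCHEMA_COLUMNS if c in df.columns]
    extra = [c for c in df.columns if c not in SCHEMA_COLUMNS]
    df = df[ordered + extra].reset_index(drop=True)
    return ReadResult(reports=df, errors=errors)


def write_line_listing(df: pd.DataFrame, path: str | Path) -> None:
    """Write the schema columns of ``df`` to CSV (internal columns dropped)."""
    cols = [c for c in SCHEMA_COLUMNS if c in df.columns]
    df[cols].to_csv(path, index=False)


def deduplicate(
    reports: pd.DataFrame, key: Sequence[str] = DEFAULT_DEDUP_KEY
) -> pd.DataFrame:
    """Drop rows that repeat an earlier row's de-duplication key.

    The first occurrence in input order is kept.  The number of removed rows is
    recorded in ``result.attrs["n_removed"]``.  Idempotent.
    """
    if reports.empty:
        out = reports.copy()
        out.attrs["n_removed"] = 0
        return out
    keyframe = pd.DataFrame(
        {
            k: _norm(reports[k]) if reports[k].dtype == object else reports[k]
            for k in key
        }
    )
    keep = ~keyframe.duplicated(keep="first")
    out = reports.loc[keep].copy()
    out.attrs["n_removed"] = int((~keep).sum())
    return out


def _apply_filter(df: pd.DataFrame, spec: FilterSpec) -> pd.Series:
    mask = pd.Series(True, index=df.index)
    categorical = {
        "age_group": spec.age_groups,
        "sex": spec.sexes,
        "route": spec.routes,
        "soc": spec.socs,
        "reaction_pt": spec.pts,
    }
    for col, allowed in categorical.items():
        if allowed is not None:
            allowed_norm = {a.strip().casefold() for a in allowed}
            mask &= _norm(df[col]).isin(allowed_norm)
    if spec.years is not None:
        lo, hi = spec.years
        mask &= (df["year"] >= lo) & (df["year"] <= hi)
    return mask


def filter_reports(
    reports: pd.DataFrame,
    spec: FilterSpec,
    *,
    deduplicate_first: bool = True,
    dedup_key: Sequence[str] = DEFAULT_DEDUP_KEY,
) -> AnalysisSet:
    """De-duplicate (optionally) and filter a listing into an analysis set.

    Provenance records the row counts along the pipeline
    (``raw`` >= ``deduplicated`` >= ``filtered``).  A spec that removes every
    row yields an empty set (with a provenance trail), not an error.
    """
    raw_n = len(reports)
    if deduplicate_first:
        deduped = deduplicate(reports, key=dedup_key)
        removed = deduped.attrs.get("n_removed", 0)
    else:
        deduped, removed = reports, 0
    mask = _apply_filter(deduped, spec)
    filtered = deduped.loc[mask].reset_index(drop=True)
    provenance = {
        "raw": raw_n,
        "deduplicated": len(deduped),
        "duplicates_removed": removed,
        "filtered": len(filtered),
        "filter_spec": spec,
    }
    return AnalysisSet(reports=filtered, spec=spec, provenance=provenance)


_COUNT_KEYS = {"reaction_pt", "soc", "drug", "year"}


def count_by(analysis_set: AnalysisSet | pd.DataFrame, key: str) -> dict:
    """Row tallies per value of ``key`` (reaction_pt, soc, drug or year).

    Each row contributes 1 to its single PT and its single SOC, so the counts
    sum to the number of rows.
    """
    if key not in _COUNT_KEYS:
        raise DataError(f"unsupported count key {key!r}; choose from {sorted(_COUNT_KEYS)}")
    df = analysis_set.reports if isinstance(analysis_set, AnalysisSet) else analysis_set
    if df.empty:
        return {}
    counts = df[key].value_counts()
    return {k: int(v) for k, v in counts.items()}
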