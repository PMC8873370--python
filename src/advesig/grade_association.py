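"""Grade-association analysis of tumor-infiltrating immune cells.

Works on cohorts of graded canine mammary carcinoma cases: histotype/grade
frequency tables, per-field infiltrate densities (CD68 macrophages, CD20
B lymphocytes, counted over a fixed number of 400x microscope fields),
between-grade two-sample t-tests computed from raw vectors or from printed
summary statistics (n, mean, SD), and serum CBC ratios (NLR, PLR).

The per-case marker value is the mean of its field counts; grade-level
statistics are computed across cases (not across pooled fields), which avoids
pseudo-replication of within-case fields.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DataError

GRADES = ("G1", "G2", "G3")

TTestVariant = Literal["welch", "pooled"]


@dataclass(frozen=True)
class CaseRecord:
    """One canine mammary tumor case."""

    case_id: str
    histotype: str
    grade: str
    field_counts: dict[str, tuple[int, ...]]
    subtype: str = ""
    serum: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.grade not in GRADES:
            raise DataError(f"grade must be one of {GRADES}, got {self.grade!r}")
        for marker, counts in self.field_counts.items():
            if any(c < 0 for c in counts):
                raise DataError(f"{marker}: field counts must be non-negative")


@dataclass(frozen=True)
class FieldProtocol:
    """Microscope field protocol: the first ``n_fields`` fields encountered
    are counted at the given magnification."""

    magnification: str = "400x"
    field_area_mm2: float = 0.1885
    n_fields: int = 10

    def __post_init__(self) -> None:
        if self.field_area_mm2 <= 0:
            raise ConfigError("field_area_mm2 must be positive")
        if self.n_fields < 1:
            raise ConfigError("n_fields must be >= 1")


@dataclass(frozen=True)
class GradeSummary:
    """Per-grade summary of a marker's per-case mean field counts."""

    grade: str
    marker: str
    n: int
    mean: float
    sd: float | None  # None when n == 1

    def __post_init__(self) -> None:
        if self.n < 1:
            raise DataError("n must be >= 1")
        if self.sd is not None and self.sd < 0:
            raise DataError("sd must be >= 0")


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    p_value: float
    variant: TTestVariant

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise DataError("p-value outside [0, 1]")
        if self.df <= 0:
            raise DataError("degrees of freedom must be positive")


def _marker_field_columns(df: pd.DataFrame, marker: str) -> list[str]:
    cols = sorted(
        (c for c in df.columns if c.startswith(f"{marker}_f")),
        key=lambda c: int(c.rsplit("f", 1)[1]),
    )
    if not cols:
        raise DataError(f"no field-count columns found for marker {marker!r}")
    return cols


def aggregate_histotype_grade(cases: pd.DataFrame) -> pd.DataFrame:
    """Histotype x grade frequency table with subtype breakdown and totals.

    One row per (histotype, subtype), columns per grade, plus ``total`` and
    ``pct`` (share of all cases, round-half-even to 1 decimal).  A final
    ``__all__`` row carries the grade marginals.  Cell counts sum to the
    number of cases.
    """
    grade_cols = list(GRADES)
    if cases.empty:
        out = pd.DataFrame(columns=["histotype", "subtype"] + grade_cols + ["total", "pct"])
        return out
    df = cases.copy()
    df["subtype"] = df.get("subtype", "").fillna("")
    ct = pd.crosstab([df["histotype"], df["subtype"]], df["grade"])
    ct = ct.reindex(columns=grade_cols, fill_value=0)
    ct = ct.reset_index()
    ct["total"] = ct[grade_cols].sum(axis=1)
    n_total = int(ct["total"].sum())
    ct["pct"] = [
        float(round(Fraction(100 * int(t), n_total), 1)) for t in ct["total"]
    ]
    marginal = {
        "histotype": "__all__",
        "subtype": "",
        **{g: int(ct[g].sum()) for g in grade_cols},
        "total": n_total,
        "pct": 100.0,
    }
    return pd.concat([ct, pd.DataFrame([marginal])], ignore_index=True)


def histotype_totals(cases: pd.DataFrame) -> pd.DataFrame:
    """Collapse the frequency table over subtypes: one row per histotype."""
    table = aggregate_histotype_grade(cases)
    body = table[table["histotype"] != "__all__"]
    n_total = int(body["total"].sum())
    grouped = body.groupby("histotype", sort=False)[list(GRADES) + ["total"]].sum().reset_index()
    grouped["pct"] = [
        float(round(Fraction(100 * int(t), n_total), 1)) if n_total else 0.0
        for t in grouped["total"]
    ]
    return grouped


def grade_percentages(counts: Sequence[int], ndigits: int = 1) -> tuple[float, ...]:
    """Percentage of cases per grade, round-half-even to ``ndigits``."""
    total = sum(int(c) for c in counts)
    if total <= 0:
        raise DataError("grade counts must sum to a positive total")
    return tuple(float(round(Fraction(100 * int(c), total), ndigits)) for c in counts)


def density_from_fields(
    field_counts: Sequence[float], protocol: FieldProtocol = FieldProtocol()
) -> tuple[float, float]:
    """Mean count per field and per mm^2 for one case's field counts."""
    if len(field_counts) != protocol.n_fields:
        raise DataError(
            f"expected {protocol.n_fields} field counts, got {len(field_counts)}"
        )
    mean = float(np.mean(field_counts))
    return mean, mean / protocol.field_area_mm2


def per_case_means(cases: pd.DataFrame, marker: str) -> pd.Series:
    """Mean field count per case for ``marker`` (index: case order)."""
    cols = _marker_field_columns(cases, marker)
    return cases[cols].mean(axis=1)


def summarize_by_grade(cases: pd.DataFrame, marker: str) -> list[GradeSummary]:
    """n / mean / SD of per-case mean field counts, per grade.

    SD is the sample standard deviation (n-1 denominator); absent for
    single-case grades.
    """
    values = per_case_means(cases, marker)
    out = []
    for grade in GRADES:
        mask = cases["grade"] == grade
        v = values[mask]
        if v.empty:
            continue
        sd = float(v.std(ddof=1)) if len(v) >= 2 else None
        out.append(GradeSummary(grade=grade, marker=marker, n=len(v), mean=float(v.mean()), sd=sd))
    return out


def ttest_summary(
    n1: int,
    mean1: float,
    sd1: float,
    n2: int,
    mean2: float,
    sd2: float,
    variant: TTestVariant = "welch",
) -> TestResult:
    """Two-sided two-sample t-test from summary statistics.

    ``welch`` uses the unequal-variance statistic with Welch-Satterthwaite
    degrees of freedom; ``pooled`` is the classical equal-variance Student
    test.  Identical summaries give t = 0, p = 1.
    """
    if n1 < 2 or n2 < 2:
        raise ConfigError("both groups need n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ConfigError("standard deviations must be >= 0")
    if sd1 == 0 and sd2 == 0:
        if mean1 == mean2:
            df = n1 + n2 - 2
            return TestResult(statistic=0.0, df=float(df), p_value=1.0, variant=variant)
        raise ConfigError("both SDs are zero with unequal means: t undefined")
    v1, v2 = sd1 * sd1, sd2 * sd2
    if variant == "welch":
        se2 = v1 / n1 + v2 / n2
        t = (mean1 - mean2) / math.sqrt(se2)
        df = se2 * se2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    elif variant == "pooled":
        df = n1 + n2 - 2
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
        t = (mean1 - mean2) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
    else:
        raise ConfigError(f"unknown t-test variant {variant!r}")
    p = 2.0 * stats.t.sf(abs(t), df)
    return TestResult(statistic=float(t), df=float(df), p_value=float(min(p, 1.0)), variant=variant)


def ttest_raw(
    x1: Sequence[float], x2: Sequence[float], variant: TTestVariant = "welch"
) -> TestResult:
    """Two-sided two-sample t-test on raw vectors (same conventions)."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    return ttest_summary(
        len(x1), float(x1.mean()), float(x1.std(ddof=1)),
        len(x2), float(x2.mean()), float(x2.std(ddof=1)),
        variant=variant,
    )


def pairwise_grade_tests(
    summaries: Sequence[GradeSummary],
    variant: TTestVariant = "welch",
    correction: Literal["none", "bonferroni", "holm"] = "none",
) -> pd.DataFrame:
    """All three between-grade comparisons for one marker.

    Returns one row per pair (G1-G2, G1-G3, G2-G3) with the t statistic,
    degrees of freedom and two-sided p-value.  No multiplicity adjustment by
    default; ``bonferroni`` or ``holm`` adds an adjusted-p column.
    """
    by_grade = {s.grade: s for s in summaries}
    missing = [g for g in GRADES if g not in by_grade]
    if missing:
        raise ConfigError(f"missing grade summaries: {missing}")
    rows = []
    for g1, g2 in itertools.combinations(GRADES, 2):
        s1, s2 = by_grade[g1], by_grade[g2]
        if s1.sd is None or s2.sd is None:
            raise ConfigError(f"SD unavailable for {g1 if s1.sd is None else g2} (n=1)")
        res = ttest_summary(s1.n, s1.mean, s1.sd, s2.n, s2.mean, s2.sd, variant=variant)
        rows.append(
            {
                "marker": s1.marker,
                "group1": g1,
                "group2": g2,
                "t": res.statistic,
                "df": res.df,
                "p_value": res.p_value,
                "variant": res.variant,
            }
        )
    out = pd.DataFrame(rows)
    if correction != "none":
        from statsmodels.stats.multitest import multipletests

        method = {"bonferroni": "bonferroni", "holm": "holm"}[correction]
        out["p_adjusted"] = multipletests(out["p_value"], method=method)[1]
    return out


def compute_cbc_ratios(
    platelet: float, lymphocyte: float, neutrophil: float
) -> tuple[float, float]:
    """Neutrophil-lymphocyte ratio and platelet-lymphocyte ratio.

    Both are scale-free serum inflammation biomarkers; inputs are counts per
    microlitre.
    """
    if lymphocyte <= 0:
        raise DataError("lymphocyte count must be positive")
    return neutrophil / lymphocyte, platelet / lymphocyte


def grade_marker_report(
    cases: pd.DataFrame,
    markers: Sequence[str] = ("cd68", "cd20m", "cd20p"),
    variant: TTestVariant = "welch",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cohort-level report: grade summaries and pairwise tests per marker."""
    summary_rows, test_frames = [], []
    for marker in markers:
        summaries = summarize_by_grade(cases, marker)
        for s in summaries:
            summary_rows.append(
                {"marker": s.marker, "grade": s.grade, "n": s.n, "mean": s.mean, "sd": s.sd}
            )
        if len(summaries) == len(GRADES):
            test_frames.append(pairwise_grade_tests(summaries, variant=variant))
    tests = (
        pd.concat(test_frames, ignore_index=True)
        if test_frames
        else pd.DataFrame(columns=["marker", "group1", "group2", "t", "df", "p_value", "variant"])
    )
    return pd.DataFrame(summary_rows), tests
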