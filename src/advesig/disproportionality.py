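"""Proportional Reporting Ratio (PRR) signal detection on 2x2 tables.

For a drug of interest within an explicit comparator class, the 2x2 table is

====  ===============================  ==================================
cell  meaning
====  ===============================  ==================================
a     reaction of interest, drug of interest
b     reaction of interest, all other drugs in the class
c     all other reactions, drug of interest
d     all other reactions, all other drugs in the class
====  ===============================  ==================================

and ``PRR = (a / (a + c)) / (b / (b + d))`` — the proportion the reaction
represents among the drug's reports relative to the same proportion among the
comparators' reports.  A drug-reaction pair is flagged as a *signal* when
PRR >= 2, at least 3 cases of the reaction are on file, and the Pearson
chi-square of the table is >= 4 (all thresholds configurable); PRR exactly 1
never signals.

Counting unit is the (report, PT) row, matching dashboard tallies.  The
comparator class is always an explicit argument, never inferred.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from fractions import Fraction
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError, DegenerateTableError
from .linelisting import AnalysisSet, _norm

ZeroPolicy = Literal["strict", "haldane"]


@dataclass(frozen=True)
class ContingencyTable:
    """The 2x2 counts a, b, c, d (see module docstring)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise DataError(f"cell {name} must be a non-negative integer, got {v!r}")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class SignalRule:
    """Multi-criterion signal definition (defaults: PRR>=2, >=3 cases, chi2>=4)."""

    prr_min: float = 2.0
    min_cases: int = 3
    chi2_min: float = 4.0

    def __post_init__(self) -> None:
        if self.prr_min < 0 or self.min_cases < 0 or self.chi2_min < 0:
            raise ConfigError("signal-rule thresholds must be non-negative")


@dataclass(frozen=True)
class PRRResult:
    """PRR, chi-square and signal status for one (drug, reaction) pair."""

    drug: str
    reaction: str
    table: ContingencyTable
    prr: float
    chi2: float
    n_cases: int
    signal: bool
    reasons: tuple[str, ...] = ()
    notes: tuple[str, ...] = ()


def prr_fraction(table: ContingencyTable) -> Fraction:
    """PRR as an exact rational; the PRR=1 exclusion compares against this."""
    if table.a + table.c == 0 or table.b + table.d == 0:
        raise DegenerateTableError("empty arm: a+c and b+d must both be positive")
    if table.b == 0:
        raise DegenerateTableError("comparator has zero reaction-of-interest reports (b=0)")
    return Fraction(table.a * (table.b + table.d), table.b * (table.a + table.c))


def compute_prr(table: ContingencyTable, zero_policy: ZeroPolicy = "strict") -> float:
    """``(a/(a+c)) / (b/(b+d))``.

    With ``zero_policy="haldane"`` and b = 0, 0.5 is added to every cell
    first (Haldane-Anscombe correction); with ``"strict"`` a b = 0 table
    raises :class:`DegenerateTableError`.  Empty arms (a+c = 0 or b+d = 0)
    always raise.
    """
    if table.a + table.c == 0 or table.b + table.d == 0:
        raise DegenerateTableError("empty arm: a+c and b+d must both be positive")
    if table.b == 0:
        if zero_policy == "strict":
            raise DegenerateTableError(
                "comparator has zero reaction-of-interest reports (b=0); "
                "use zero_policy='haldane' to apply a +0.5 correction"
            )
        a, b, c, d = (x + 0.5 for x in (table.a, table.b, table.c, table.d))
        return (a / (a + c)) / (b / (b + d))
    return float(prr_fraction(table))


def compute_chi2(table: ContingencyTable, yates: bool = False) -> float:
    """Pearson chi-square of the 2x2 table.

    ``N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d))``; with ``yates=True`` the
    continuity correction reduces ``|ad - bc|`` by N/2, floored at 0.  Tables
    with any zero margin return 0 (degenerate; no association measurable).
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n = a + b + c + d
    margins = ((a + b), (c + d), (a + c), (b + d))
    if any(m == 0 for m in margins):
        return 0.0
    cross = abs(a * d - b * c)
    if yates:
        cross = max(cross - n / 2.0, 0.0)
    denom = math.prod(margins)
    return n * cross * cross / denom


def chi2_is_degenerate(table: ContingencyTable) -> bool:
    a, b, c, d = table.a, table.b, table.c, table.d
    return min(a + b, c + d, a + c, b + d) == 0


def evaluate_signal(
    prr: float | Fraction,
    n_cases: int,
    chi2: float,
    rule: SignalRule = SignalRule(),
) -> tuple[bool, tuple[str, ...]]:
    """Apply the multi-criterion signal rule.

    Returns ``(signal, reasons)`` where ``reasons`` lists every failed
    criterion (``"prr_min"``, ``"min_cases"``, ``"chi2_min"``, ``"prr_unity"``).
    A PRR of exactly 1 never signals; pass a :class:`~fractions.Fraction`
    (e.g. from :func:`prr_fraction`) for an exact unity test.
    """
    for name, v in (("prr", prr), ("n_cases", n_cases), ("chi2", chi2)):
        if v < 0 or not math.isfinite(float(v)):
            raise DataError(f"{name} must be finite and non-negative, got {v}")
    reasons = []
    if prr < rule.prr_min:
        reasons.append("prr_min")
    if n_cases < rule.min_cases:
        reasons.append("min_cases")
    if chi2 < rule.chi2_min:
        reasons.append("chi2_min")
    if prr == 1:
        reasons.append("prr_unity")
    return (not reasons, tuple(reasons))


def reaction_share(count: int, total: int, ndigits: int = 1) -> float:
    """Percentage share ``100 * count / total``, rounded half-even.

    This is the per-PT share of a SOC's reports, e.g. the share platelet
    count decrease represents among a drug's blood-and-lymphatic reports.
    """
    if total <= 0:
        raise DataError("total must be positive")
    if not 0 <= count <= total:
        raise DataError(f"count {count} outside [0, {total}]")
    # exact rational arithmetic so round-half-even is applied to the true value
    return float(round(Fraction(100 * count, total), ndigits))


def build_contingency(
    analysis_set: AnalysisSet | pd.DataFrame,
    drug: str,
    reaction: str,
    class_drugs: Sequence[str],
    *,
    level: Literal["reaction_pt", "soc"] = "reaction_pt",
) -> ContingencyTable:
    """Count the 2x2 cells for ``(drug, reaction)`` within ``class_drugs``.

    ``level`` selects whether ``reaction`` is a preferred term or a system
    organ class.  Matching is case-insensitive.
    """
    df = analysis_set.reports if isinstance(analysis_set, AnalysisSet) else analysis_set
    class_norm = [d.strip().casefold() for d in class_drugs]
    drug_norm = drug.strip().casefold()
    if drug_norm not in class_norm:
        raise ConfigError(f"drug {drug!r} is not in class_drugs")
    if len(set(class_norm)) < 2:
        raise ConfigError("class_drugs must contain the drug of interest and >=1 comparator")
    drugs = _norm(df["drug"])
    reactions = _norm(df[level])
    in_class = drugs.isin(class_norm)
    is_drug = drugs == drug_norm
    is_reaction = reactions == reaction.strip().casefold()
    a = int((in_class & is_drug & is_reaction).sum())
    c = int((in_class & is_drug & ~is_reaction).sum())
    b = int((in_class & ~is_drug & is_reaction).sum())
    d = int((in_class & ~is_drug & ~is_reaction).sum())
    return ContingencyTable(a=a, b=b, c=c, d=d)


def _screen_tables(
    df: pd.DataFrame, class_drugs: Sequence[str], level: str, reactions: Sequence[str] | None
) -> list[tuple[str, str, ContingencyTable]]:
    """All (drug, reaction, table) triples via one cross-tabulation."""
    drugs_norm = _norm(df["drug"])
    class_norm = {d.strip().casefold(): d.strip() for d in class_drugs}
    sub = df.loc[drugs_norm.isin(class_norm)].copy()
    sub["_drug"] = drugs_norm.loc[sub.index]
    sub["_reaction"] = _norm(sub[level])
    ct = pd.crosstab(sub["_drug"], sub["_reaction"])
    ct = ct.reindex(sorted(class_norm), fill_value=0)
    row_tot = ct.sum(axis=1)
    col_tot = ct.sum(axis=0)
    grand = int(ct.values.sum())
    if reactions is not None:
        wanted = [r.strip().casefold() for r in reactions]
    else:
        wanted = list(ct.columns)
    triples = []
    for dn in ct.index:
        for rn in wanted:
            a = int(ct.at[dn, rn]) if rn in ct.columns else 0
            col = int(col_tot.get(rn, 0))
            row = int(row_tot[dn])
            b = col - a
            c = row - a
            d = grand - row - col + a
            triples.append((class_norm[dn], rn, ContingencyTable(a=a, b=b, c=c, d=d)))
    return triples


def prr_screen(
    analysis_set: AnalysisSet | pd.DataFrame,
    class_drugs: Sequence[str],
    reactions: Sequence[str] | None = None,
    *,
    level: Literal["reaction_pt", "soc"] = "reaction_pt",
    rule: SignalRule = SignalRule(),
    zero_policy: ZeroPolicy = "strict",
    yates: bool = False,
) -> pd.DataFrame:
    """Screen every (class drug, reaction) pair and apply the signal rule.

    Returns a DataFrame with columns ``drug, reaction, a, b, c, d, prr, chi2,
    n_cases, signal, reasons, notes``, sorted by drug then descending PRR.
    Reaction labels are reported in their casefolded (lower-case) form, since
    rows differing only in case are tallied together.
    Degenerate tables are flagged in ``notes`` (never fatal): an undefined PRR
    under the strict zero policy is reported as NaN with ``signal=False``.
    """
    df = analysis_set.reports if isinstance(analysis_set, AnalysisSet) else analysis_set
    class_norm = [d.strip().casefold() for d in class_drugs]
    if len(set(class_norm)) < 2:
        raise ConfigError("need >= 2 class drugs to form a comparator")
    rows = []
    for drug, reaction, table in _screen_tables(df, class_drugs, level, reactions):
        notes = []
        prr_value: float | Fraction
        try:
            prr_exact = prr_fraction(table) if table.b > 0 else None
            prr = compute_prr(table, zero_policy=zero_policy)
            prr_value = prr_exact if prr_exact is not None else prr
        except DegenerateTableError as exc:
            prr, prr_value = float("nan"), float("nan")
            notes.append(f"prr_undefined: {exc}")
        chi2 = compute_chi2(table, yates=yates)
        if chi2_is_degenerate(table):
            notes.append("chi2_degenerate_margin")
        if math.isnan(prr):
            signal, reasons = False, ("prr_undefined",)
        else:
            signal, reasons = evaluate_signal(prr_value, table.a, chi2, rule)
        rows.append(
            {
                "drug": drug,
                "reaction": reaction,
                "a": table.a,
                "b": table.b,
                "c": table.c,
                "d": table.d,
                "prr": prr,
                "chi2": chi2,
                "n_cases": table.a,
                "signal": signal,
                "reasons": ";".join(reasons),
                "notes": ";".join(notes),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "drug", "reaction", "a", "b", "c", "d",
            "prr", "chi2", "n_cases", "signal", "reasons", "notes",
        ],
    )
    return out.sort_values(
        ["drug", "prr"], ascending=[True, False], na_position="last", kind="mergesort"
    ).reset_index(drop=True)


@dataclass
class OperatingCharacteristics:
    """Monte-Carlo operating characteristics of a signal rule."""

    pairs: pd.DataFrame  # per (drug, reaction): truth and estimates
    power: float
    power_se: float
    false_positive_rate: float
    false_positive_rate_se: float
    n_replicates: int


def operating_characteristics(
    config,
    rule: SignalRule = SignalRule(),
    n_replicates: int = 100,
    seed: int = 0,
    *,
    zero_policy: ZeroPolicy = "haldane",
    yates: bool = False,
) -> OperatingCharacteristics:
    """Estimate false-positive rate, power and PRR bias under a known truth.

    Each replicate simulates a line listing from ``config`` (a
    :class:`~advesig.synthetic_data.SyntheticPVConfig`), screens every
    (drug, reaction) pair, and records the PRR estimate and signal flag.
    Pairs with an injected multiplier != 1 are "true" signals; all others are
    null.  Estimates come with binomial / empirical standard errors and are
    deterministic given ``seed``.

    The listing is screened as simulated (the harness uses configs without
    duplicate injection; the surrogate de-duplication key would collapse
    genuinely distinct reports that share coarse demographics and bias the
    recovery).
    """
    from .synthetic_data import expected_prr, simulate_line_listing

    if n_replicates < 1:
        raise ConfigError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    child_seeds = rng.integers(0, 2**31 - 1, size=n_replicates)
    lam = {(d.casefold(), r.casefold()): m for d, r, m in config.signals}
    pts = [pt for pt, _ in config.reactions]
    keys = [(drug, pt) for drug in config.drugs for pt in pts]
    prr_samples: dict[tuple[str, str], list[float]] = {k: [] for k in keys}
    flag_samples: dict[tuple[str, str], list[bool]] = {k: [] for k in keys}
    for s in child_seeds:
        listing = simulate_line_listing(replace(config, seed=int(s)))
        screen = prr_screen(
            listing,
            class_drugs=list(config.drugs),
            reactions=pts,
            rule=rule,
            zero_policy=zero_policy,
            yates=yates,
        )
        idx = {(row.drug.casefold(), row.reaction.casefold()): row for row in screen.itertuples()}
        for drug, pt in keys:
            row = idx[(drug.casefold(), pt.casefold())]
            prr_samples[(drug, pt)].append(row.prr)
            flag_samples[(drug, pt)].append(bool(row.signal))

    records = []
    for drug, pt in keys:
        mult = lam.get((drug.casefold(), pt.casefold()), 1.0)
        prrs = np.asarray(prr_samples[(drug, pt)], dtype=float)
        flags = np.asarray(flag_samples[(drug, pt)], dtype=bool)
        finite = prrs[np.isfinite(prrs)]
        mean_prr = float(finite.mean()) if finite.size else float("nan")
        se_prr = (
            float(finite.std(ddof=1) / math.sqrt(finite.size)) if finite.size > 1 else float("nan")
        )
        rate = float(flags.mean())
        rate_se = math.sqrt(rate * (1 - rate) / n_replicates)
        try:
            truth = expected_prr(config, drug, pt)
        except DataError:
            truth = float("nan")
        records.append(
            {
                "drug": drug,
                "reaction": pt,
                "multiplier": mult,
                "expected_prr": truth,
                "mean_prr": mean_prr,
                "se_prr": se_prr,
                "prr_bias": mean_prr - truth,
                "flag_rate": rate,
                "flag_rate_se": rate_se,
                "is_signal_pair": mult != 1.0,
            }
        )
    pairs = pd.DataFrame(records)
    signal_pairs = pairs[pairs["is_signal_pair"]]
    null_pairs = pairs[~pairs["is_signal_pair"]]

    def _pooled(sub: pd.DataFrame) -> tuple[float, float]:
        if sub.empty:
            return float("nan"), float("nan")
        p = float(sub["flag_rate"].mean())
        n_flags = len(sub) * n_replicates
        return p, math.sqrt(p * (1 - p) / n_flags)

    power, power_se = _pooled(signal_pairs)
    fpr, fpr_se = _pooled(null_pairs)
    return OperatingCharacteristics(
        pairs=pairs,
        power=power,
        power_se=power_se,
        false_positive_rate=fpr,
        false_positive_rate_se=fpr_se,
        n_replicates=n_replicates,
    )
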