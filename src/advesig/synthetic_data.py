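"""Synthetic spontaneous-report line listings and canine-IHC cohorts.

Two generators with known ground truth back the whole test surface:

* :func:`simulate_line_listing` emits a pharmacovigilance line listing (one
  row per (report, reaction)) from per-drug report volumes, per-reaction
  baseline reporting probabilities and injected drug-reaction signal
  multipliers λ.  :func:`expected_prr` gives the exact PRR implied by the
  configuration, in closed form, for parameter-recovery tests.
* :func:`simulate_ihc_cohort` emits a cohort of graded canine mammary
  carcinoma cases with per-field CD68/CD20 infiltrate counts and serum CBC
  values, parameterised by per-grade means and standard deviations.

Both draw from one seeded :class:`numpy.random.Generator` per call; identical
configuration and seed give byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .linelisting import SCHEMA_COLUMNS

# ---------------------------------------------------------------------------
# spontaneous-report generator

#: Demographic distributions used when a config does not override them.
#: Categories mirror dashboard granularity (age bands, not numeric age).
DEFAULT_DEMOGRAPHICS: dict[str, dict] = {
    "age_group": {"18-64": 0.75, "65-85": 0.20, "0-17": 0.05},
    "sex": {"female": 0.90, "male": 0.10},
    "route": {"i.v.": 0.60, "s.c.": 0.25, "unknown": 0.15},
    "year": {y: 1 / 6 for y in range(2015, 2021)},
    "outcome": {
        "recovered": 0.45,
        "not recovered": 0.25,
        "drug withdrawn": 0.15,
        "unknown": 0.15,
    },
}


@dataclass(frozen=True)
class SyntheticPVConfig:
    """Generative specification for a synthetic line listing.

    Parameters
    ----------
    drugs
        Unique drug labels.
    totals
        Reports generated per drug (exact counts, before duplicate injection).
    reactions
        ``(preferred term, system organ class)`` vocabulary.
    baseline_probs
        Per-PT probability of appearing on any given report; reactions are
        sampled independently per report, with at least one guaranteed (an
        all-empty draw is redrawn).
    signals
        ``(drug, reaction, multiplier)`` entries; the multiplier λ >= 0 scales
        that pair's baseline probability (capped at 1).  λ = 1 is the null.
    demographics
        Categorical distributions for ``age_group``, ``sex``, ``route``,
        ``year`` and ``outcome``; missing keys fall back to
        :data:`DEFAULT_DEMOGRAPHICS`.
    duplicate_rate
        Probability in [0, 1) that a report is emitted twice with a fresh
        identifier; duplicate rows carry the original id in a ``dup_of``
        column so the true de-duplicated set is recoverable.
    serious_prob
        Probability a report is marked serious.
    seed
        Seed for the single generator used by the simulation.
    """

    drugs: tuple[str, ...]
    totals: Mapping[str, int]
    reactions: tuple[tuple[str, str], ...]
    baseline_probs: Mapping[str, float]
    signals: tuple[tuple[str, str, float], ...] = ()
    demographics: Mapping[str, Mapping] = field(default_factory=dict)
    duplicate_rate: float = 0.0
    serious_prob: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "drugs", tuple(self.drugs))
        object.__setattr__(
            self, "reactions", tuple((pt, soc) for pt, soc in self.reactions)
        )
        object.__setattr__(
            self, "signals", tuple((d, r, float(m)) for d, r, m in self.signals)
        )
        if len(set(self.drugs)) != len(self.drugs):
            raise ConfigError("drug labels must be unique")
        if not self.drugs or not self.reactions:
            raise ConfigError("need at least one drug and one reaction")
        pts = [pt for pt, _ in self.reactions]
        if len(set(pts)) != len(pts):
            raise ConfigError("reaction PTs must be unique")
        for drug in self.drugs:
            n = self.totals.get(drug)
            if n is None or int(n) <= 0:
                raise ConfigError(f"totals[{drug!r}] must be a positive integer")
        for pt in pts:
            p = self.baseline_probs.get(pt)
            if p is None or not (0.0 < p <= 1.0):
                raise ConfigError(f"baseline_probs[{pt!r}] must lie in (0, 1]")
        seen = set()
        for drug, pt, mult in self.signals:
            if drug not in self.drugs:
                raise ConfigError(f"signal references unknown drug {drug!r}")
            if pt not in pts:
                raise ConfigError(f"signal references unknown reaction {pt!r}")
            if mult < 0:
                raise ConfigError("signal multiplier must be >= 0")
            if (drug, pt) in seen:
                raise ConfigError(f"duplicate signal entry for ({drug!r}, {pt!r})")
            seen.add((drug, pt))
        if not 0.0 <= self.duplicate_rate < 1.0:
            raise ConfigError("duplicate_rate must lie in [0, 1)")
        if not 0.0 <= self.serious_prob <= 1.0:
            raise ConfigError("serious_prob must lie in [0, 1]")
        for key, dist in self.demographics.items():
            if key not in DEFAULT_DEMOGRAPHICS:
                raise ConfigError(f"unknown demographic field {key!r}")
            total = float(sum(dist.values()))
            if not math.isclose(total, 1.0, rel_tol=1e-9, abs_tol=1e-9):
                raise ConfigError(f"demographics[{key!r}] probabilities sum to {total}, not 1")

    def effective_probs(self, drug: str) -> np.ndarray:
        """Per-reaction presence probabilities for ``drug``, multipliers applied."""
        pts = [pt for pt, _ in self.reactions]
        p = np.array([self.baseline_probs[pt] for pt in pts], dtype=float)
        for sd, spt, mult in self.signals:
            if sd == drug:
                p[pts.index(spt)] = min(1.0, self.baseline_probs[spt] * mult)
        return p


def _sample_categorical(rng: np.random.Generator, dist: Mapping, size: int) -> np.ndarray:
    values = list(dist.keys())
    probs = np.asarray(list(dist.values()), dtype=float)
    idx = rng.choice(len(values), size=size, p=probs / probs.sum())
    return np.asarray(values, dtype=object)[idx]


def simulate_line_listing(config: SyntheticPVConfig) -> pd.DataFrame:
    """Draw a synthetic line listing.

    Returns a DataFrame in the line-listing schema plus a ``dup_of`` column:
    empty for original reports, the source ``report_id`` for injected
    duplicate copies (exact payload copies under a fresh identifier).
    Reports with no sampled reaction are redrawn, so every report carries at
    least one PT, as in real listings.
    """
    rng = np.random.default_rng(config.seed)
    demographics = {**DEFAULT_DEMOGRAPHICS, **dict(config.demographics)}
    pts = np.asarray([pt for pt, _ in config.reactions], dtype=object)
    socs = np.asarray([soc for _, soc in config.reactions], dtype=object)
    frames = []
    counter = 0
    for drug in config.drugs:
        n = int(config.totals[drug])
        p = config.effective_probs(drug)
        present = rng.random((n, len(pts))) < p
        empty = ~present.any(axis=1)
        while empty.any():  # guarantee >= 1 reaction per report
            present[empty] = rng.random((int(empty.sum()), len(pts))) < p
            empty = ~present.any(axis=1)
        demo = {k: _sample_categorical(rng, demographics[k], n) for k in demographics}
        serious = rng.random(n) < config.serious_prob
        ids = np.asarray([f"R{counter + i:08d}" for i in range(n)], dtype=object)
        counter += n
        rep_idx, reac_idx = np.nonzero(present)
        frame = pd.DataFrame(
            {
                "report_id": ids[rep_idx],
                "drug": drug,
                "reaction_pt": pts[reac_idx],
                "soc": socs[reac_idx],
                "age_group": demo["age_group"][rep_idx],
                "sex": demo["sex"][rep_idx],
                "route": demo["route"][rep_idx],
                "year": demo["year"][rep_idx].astype(int),
                "serious": serious[rep_idx],
                "outcome": demo["outcome"][rep_idx],
                "concomitant": "",
                "dup_of": "",
            }
        )
        if config.duplicate_rate > 0:
            dup_mask = rng.random(n) < config.duplicate_rate
            dup_reports = np.nonzero(dup_mask)[0]
            if dup_reports.size:
                new_ids = {
                    int(i): f"R{counter + k:08d}" for k, i in enumerate(dup_reports)
                }
                counter += dup_reports.size
                copies = frame[np.isin(rep_idx, dup_reports)].copy()
                src = copies["report_id"].to_numpy(dtype=object)
                copy_rep = rep_idx[np.isin(rep_idx, dup_reports)]
                copies["report_id"] = [new_ids[int(i)] for i in copy_rep]
                copies["dup_of"] = src
                frame = pd.concat([frame, copies], ignore_index=True)
        frames.append(frame)
    out = pd.concat(frames, ignore_index=True)
    return out[SCHEMA_COLUMNS + ["dup_of"]]


def true_deduplicated(listing: pd.DataFrame) -> pd.DataFrame:
    """The generator's ground-truth original reports (injected copies removed)."""
    if "dup_of" not in listing.columns:
        return listing
    return listing.loc[listing["dup_of"] == ""].reset_index(drop=True)


def expected_prr(config: SyntheticPVConfig, drug: str, reaction: str) -> float:
    """Closed-form PRR implied by the configuration.

    Expected (report, PT) row counts per drug are ``N_d * f_d * p_{d,r}``
    where ``f_d = 1 / (1 - prod_r (1 - p_{d,r}))`` is the inflation from the
    at-least-one-reaction guarantee (an all-empty reaction vector is redrawn,
    which scales every presence probability of that drug by the same factor).
    The PRR is then the drug's expected row proportion of the reaction over
    the comparator pool's.  Duplicate injection multiplies every count by the
    same factor and cancels.
    """
    pts = [pt for pt, _ in config.reactions]
    if drug not in config.drugs:
        raise ConfigError(f"unknown drug {drug!r}")
    if reaction not in pts:
        raise ConfigError(f"unknown reaction {reaction!r}")
    r = pts.index(reaction)
    a = c = b = d = 0.0
    for dr in config.drugs:
        p = config.effective_probs(dr)
        n = float(config.totals[dr])
        q0 = float(np.prod(1.0 - p))
        f = 1.0 / (1.0 - q0) if q0 < 1.0 else 1.0
        rows_r = n * f * p[r]
        rows_other = n * f * (p.sum() - p[r])
        if dr == drug:
            a, c = rows_r, rows_other
        else:
            b += rows_r
            d += rows_other
    if b + d == 0:
        raise ConfigError("config has no comparator drugs")
    if b == 0:
        raise DataError(
            f"comparator pool has zero expected {reaction!r} reports; PRR undefined"
        )
    return (a / (a + c)) / (b / (b + d))


# ---------------------------------------------------------------------------
# canine-IHC cohort generator

GRADES = ("G1", "G2", "G3")
MARKERS = ("cd68", "cd20m", "cd20p")
SERUM_PARAMS = ("platelet", "lymphocyte", "neutrophil")

#: Histotype marginal frequencies of the reference cohort of 101 canine
#: mammary carcinomas (simple-carcinoma subtypes broken out).
DEFAULT_HISTOTYPE_WEIGHTS: dict[tuple[str, str | None], int] = {
    ("simple carcinoma", "tubulopapillary"): 37,
    ("simple carcinoma", "cystic-papillary"): 41,
    ("simple carcinoma", "tubular"): 5,
    ("simple carcinoma", "cribriform"): 2,
    ("comedocarcinoma", None): 7,
    ("micropapillary invasive", None): 2,
    ("anaplastic", None): 2,
    ("intraductal papillary", None): 4,
    ("solid", None): 1,
}

#: Per-grade per-field infiltrate count parameters (mean, SD) at 400x
#: magnification (0.1885 mm^2 fields), from the reference cohort.
DEFAULT_MARKER_PARAMS: dict[str, dict[str, tuple[float, float]]] = {
    "cd68": {"G1": (6.0, 4.24), "G2": (26.0, 18.38), "G3": (46.5, 24.64)},
    "cd20m": {"G1": (39.5, 10.2), "G2": (34.13, 9.1), "G3": (30.13, 4.1)},
    "cd20p": {"G1": (48.1, 11.2), "G2": (42.13, 9.1), "G3": (36.3, 8.5)},
}

#: Per-grade serum CBC parameters (mean, SD), counts per microlitre.
DEFAULT_SERUM_PARAMS: dict[str, dict[str, tuple[float, float]]] = {
    "platelet": {"G1": (221000.0, 20000.0), "G2": (295000.0, 30000.0), "G3": (381000.0, 40000.0)},
    "lymphocyte": {"G1": (4001.1, 800.0), "G2": (2060.0, 600.0), "G3": (2721.1, 1100.0)},
    "neutrophil": {"G1": (5432.0, 1000.0), "G2": (8692.0, 432.0), "G3": (11200.0, 6300.0)},
}

#: Grade case counts of the reference cohort.
DEFAULT_GRADE_COUNTS = {"G1": 45, "G2": 34, "G3": 22}


@dataclass(frozen=True)
class SyntheticIHCConfig:
    """Generative specification for a graded canine-IHC cohort.

    ``marker_params[marker][grade] = (mean, sd)`` parameterises the per-field
    count distribution of that marker in that grade; one latent value is drawn
    per case and replicated across its ``n_fields`` fields (``field_sd`` adds
    optional within-case field noise).  With ``count_model="truncnorm"`` the
    latent value is a normal draw truncated at 0; ``"negbin"`` uses a negative
    binomial matched to the mean/SD (Poisson when SD^2 <= mean).  ``serum_n``
    limits how many cases per grade carry serum CBC values (the rest are NaN),
    mirroring cohorts where haematology is available for a subset only.
    """

    grade_counts: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GRADE_COUNTS)
    )
    marker_params: Mapping[str, Mapping[str, tuple[float, float]]] = field(
        default_factory=lambda: {m: dict(v) for m, v in DEFAULT_MARKER_PARAMS.items()}
    )
    serum_params: Mapping[str, Mapping[str, tuple[float, float]]] = field(
        default_factory=lambda: {p: dict(v) for p, v in DEFAULT_SERUM_PARAMS.items()}
    )
    serum_n: int | None = 4
    n_fields: int = 10
    count_model: Literal["truncnorm", "negbin"] = "truncnorm"
    field_sd: float = 0.0
    histotype_weights: Mapping[tuple[str, str | None], float] = field(
        default_factory=lambda: dict(DEFAULT_HISTOTYPE_WEIGHTS)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fields < 1:
            raise ConfigError("n_fields must be >= 1")
        if self.field_sd < 0:
            raise ConfigError("field_sd must be >= 0")
        if self.count_model not in ("truncnorm", "negbin"):
            raise ConfigError(f"unknown count_model {self.count_model!r}")
        for g, n in self.grade_counts.items():
            if g not in GRADES:
                raise ConfigError(f"unknown grade {g!r}")
            if int(n) < 0:
                raise ConfigError(f"grade_counts[{g!r}] must be >= 0")
        for params in (self.marker_params, self.serum_params):
            for name, per_grade in params.items():
                for g, (mean, sd) in per_grade.items():
                    if sd < 0:
                        raise ConfigError(f"{name}/{g}: SD must be >= 0, got {sd}")
        if self.serum_n is not None and self.serum_n < 0:
            raise ConfigError("serum_n must be >= 0 or None")


def _draw_case_values(
    rng: np.random.Generator, mean: float, sd: float, n: int, model: str
) -> np.ndarray:
    """One non-negative latent count level per case."""
    if n == 0:
        return np.empty(0)
    if sd == 0:
        return np.full(n, float(mean))
    if model == "truncnorm":
        from scipy.stats import truncnorm

        a = (0.0 - mean) / sd
        return truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=n, random_state=rng)
    var = sd * sd
    if var <= mean:  # negative binomial needs overdispersion
        return rng.poisson(mean, size=n).astype(float)
    p = mean / var
    r = mean * mean / (var - mean)
    return rng.negative_binomial(r, p, size=n).astype(float)


def simulate_ihc_cohort(config: SyntheticIHCConfig) -> pd.DataFrame:
    """Draw a synthetic cohort, one row per case.

    Columns: ``case_id, histotype, subtype, grade``, per-field count columns
    ``<marker>_f1 .. _f<n_fields>`` for each marker, and serum ``platelet,
    lymphocyte, neutrophil`` (NaN beyond ``serum_n`` cases per grade).
    """
    rng = np.random.default_rng(config.seed)
    hist_keys = list(config.histotype_weights.keys())
    hist_w = np.asarray([config.histotype_weights[k] for k in hist_keys], dtype=float)
    hist_w = hist_w / hist_w.sum()
    rows: list[dict] = []
    case_no = 0
    for grade in GRADES:
        n = int(config.grade_counts.get(grade, 0))
        if n == 0:
            continue
        hist_idx = rng.choice(len(hist_keys), size=n, p=hist_w)
        marker_fields: dict[str, np.ndarray] = {}
        for marker in config.marker_params:
            mean, sd = config.marker_params[marker][grade]
            case_vals = _draw_case_values(rng, mean, sd, n, config.count_model)
            fields = np.repeat(case_vals[:, None], config.n_fields, axis=1)
            if config.field_sd > 0:
                fields = fields + rng.normal(0.0, config.field_sd, size=fields.shape)
            marker_fields[marker] = np.clip(np.rint(fields), 0, None).astype(int)
        serum_vals: dict[str, np.ndarray] = {}
        for param in config.serum_params:
            mean, sd = config.serum_params[param][grade]
            v = rng.normal(mean, sd, size=n) if sd > 0 else np.full(n, mean)
            v = np.clip(v, 0.0, None)
            if config.serum_n is not None:
                v[config.serum_n :] = np.nan
            serum_vals[param] = v
        for i in range(n):
            histotype, subtype = hist_keys[hist_idx[i]]
            row = {
                "case_id": f"C{case_no:04d}",
                "histotype": histotype,
                "subtype": subtype if subtype is not None else "",
                "grade": grade,
            }
            case_no += 1
            for marker, fields in marker_fields.items():
                for j in range(config.n_fields):
                    row[f"{marker}_f{j + 1}"] = int(fields[i, j])
            for param, v in serum_vals.items():
                row[param] = float(v[i])
            rows.append(row)
    return pd.DataFrame(rows)


def write_ihc_cohort(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_ihc_cohort(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False, na_values=[""])
    for col in ("case_id", "histotype", "subtype", "grade"):
        df[col] = df[col].fillna("").astype(str).str.strip()
    return df


def recovery_config(
    multiplier: float = 5.0,
    baseline: float = 0.05,
    reports_per_drug: int = 20000,
    n_reactions: int = 8,
    duplicate_rate: float = 0.0,
    seed: int = 0,
) -> SyntheticPVConfig:
    """Parameter-recovery harness configuration.

    Three drugs (one of interest, two comparators) with an ``n_reactions``-PT
    vocabulary at a common baseline probability, and one injected signal
    (``drug_a``, ``reaction_01``) with the given multiplier.  Used by the
    operating-characteristics harness; :func:`expected_prr` gives the exact
    PRR the screen should recover.
    """
    pts = [f"reaction_{i + 1:02d}" for i in range(n_reactions)]
    socs = ["SOC A" if i % 2 == 0 else "SOC B" for i in range(n_reactions)]
    drugs = ("drug_a", "drug_b", "drug_c")
    return SyntheticPVConfig(
        drugs=drugs,
        totals={d: reports_per_drug for d in drugs},
        reactions=tuple(zip(pts, socs)),
        baseline_probs={pt: baseline for pt in pts},
        signals=(("drug_a", "reaction_01", multiplier),),
        duplicate_rate=duplicate_rate,
        seed=seed,
    )


def default_pv_config(seed: int = 0) -> SyntheticPVConfig:
    """A three-drug demonstration configuration.

    Report volumes are on the scale of an anti-HER2 monoclonal-antibody class
    in a large spontaneous-report database; the vocabulary mixes blood-count,
    administration-site, immune-system and product-issue terms.  No signal is
    injected (all multipliers 1); pass ``signals`` to a copy for recovery
    experiments.
    """
    blood = "Blood and lymphatic system disorders"
    general = "General disorders and administration site conditions"
    immune = "Immune system disorders"
    reactions = (
        ("platelet count decrease", blood),
        ("neutrophil count decrease", blood),
        ("lymphocyte count decrease", blood),
        ("oedema", general),
        ("erythema", general),
        ("drug ineffective", general),
        ("cytokine release syndrome", immune),
        ("product issue", "Product issues"),
        ("nausea", "Gastrointestinal disorders"),
        ("fatigue", general),
    )
    baseline = {
        "platelet count decrease": 0.06,
        "neutrophil count decrease": 0.08,
        "lymphocyte count decrease": 0.02,
        "oedema": 0.10,
        "erythema": 0.08,
        "drug ineffective": 0.12,
        "cytokine release syndrome": 0.01,
        "product issue": 0.02,
        "nausea": 0.30,
        "fatigue": 0.35,
    }
    return SyntheticPVConfig(
        drugs=("trastuzumab", "pertuzumab", "trastuzumab emtansine"),
        totals={"trastuzumab": 12711, "pertuzumab": 3230, "trastuzumab emtansine": 1345},
        reactions=reactions,
        baseline_probs=baseline,
        duplicate_rate=0.02,
        seed=seed,
    )
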