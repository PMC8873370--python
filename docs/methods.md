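# Methods

## Scope and data model

`advesig` implements two analysis strands that share nothing but a
statistical habit of working from counts:

1. **Disproportionality screening** of spontaneous ADR line listings —
   one row per (report, reaction preferred term), with system organ class
   (SOC), coarse demographics (age band, sex, route), report year,
   seriousness and outcome. Multi-PT reports span several rows sharing a
   `report_id`; PT-level tallies count rows, which matches how dashboard
   exports are tallied in practice.
2. **Grade association** in a cohort of graded canine mammary carcinomas —
   one row per case, with histotype/subtype, grade G1–G3, ten per-field
   counts per immunostain marker (CD68 macrophages, CD20 B cells with
   monoclonal and polyclonal antibodies), and serum CBC values.

Both strands are backed by synthetic generators with analytically known
ground truth, so every pipeline stage is testable offline.

## PRR and the signal rule

For drug *D* within an explicit comparator class, the 2×2 table (a, b, c, d)
counts reaction-of-interest vs. all-other-reaction rows for *D* vs. the rest
of the class, and PRR = (a/(a+c)) / (b/(b+d)). Decisions that matter:

* **Comparator is always explicit.** The class is an argument
  (`class_drugs`), never inferred from the data, so the same listing can be
  screened against different comparator sets.
* **PRR = 1 exclusion is exact.** The rule "PRR of exactly 1 never
  signals" is evaluated on the rational value a(b+d) / b(a+c)
  (`fractions.Fraction`), not on a float within tolerance. Equal-proportion
  tables therefore never signal regardless of scale.
* **χ² variant.** Pearson without continuity correction by default, with a
  `yates` flag (classical PRR practice is split; both are tested against
  `scipy.stats.chi2_contingency`). The rule's χ² ≥ 4 threshold applies to
  whichever variant the run configured. Tables with a zero margin report
  χ² = 0 with a degeneracy flag.
* **Zero-cell policy.** `strict` (default) raises on b = 0 rather than
  silently correcting, because +0.5 corrections distort PRR most exactly
  where tables are near-degenerate; `haldane` adds 0.5 to all four cells.
  In batch screening a strict-policy failure becomes a per-row flag
  (`prr_undefined`), never an exception.
* **Rounding.** Percentage shares use round-half-even on the exact rational
  100·count/total, at a configurable number of digits (default 1). Some
  published percentage tables are truncated rather than rounded (e.g. a
  grade distribution of 45/34/22 out of 101 printed as 44.5/33.6/21.7 where
  half-even gives 44.6/33.7/21.8); this package always rounds and documents
  the divergence rather than emulating truncation.

## De-duplication

Published analyses of dashboard exports remove duplicate reports manually;
that step is not reproducible. The substitute is a deterministic surrogate
key — (drug, PT, age band, sex, route, year, seriousness), compared
case-insensitively after trimming — keeping the first occurrence in input
order. This is documented, configurable, and idempotent, but it is a
*surrogate*: with coarse categorical demographics, genuinely distinct
reports collide once a stratum fills up. Consequences:

* On large synthetic listings (≳10³ reports per drug) the key saturates and
  flattens real disproportionality; the Monte-Carlo recovery harness and the
  end-to-end synthetic example therefore screen un-deduplicated listings
  (their generator configs inject no duplicates), and the pipeline exposes a
  `deduplicate` toggle.
* The generator's injected duplicates are exact payload copies under fresh
  identifiers, so de-duplicating a full listing provably equals
  de-duplicating the generator's true original set — which is what the tests
  assert.

## Synthetic line-listing generator

Each drug contributes an exact, configured number of reports. Reactions are
sampled independently per report from per-PT probabilities (signal
multipliers λ scale a pair's probability, capped at 1); demographics are
drawn from categorical distributions; a `duplicate_rate` fraction of reports
is re-emitted verbatim under a new identifier. One seeded
`numpy.random.Generator` per call; identical config + seed gives
byte-identical CSV.

**At-least-one-reaction guarantee.** Real reports exist because something
was reported, so all-empty reaction draws are redrawn. Conditioning on
non-emptiness inflates every reaction-presence probability of a drug by the
same factor 1/(1 − ∏ᵣ(1 − pᵣ)). Because the factor is common within a drug,
the closed-form PRR oracle (`expected_prr`) applies it exactly to every
expected count and remains exact under the redraw scheme. Empirical
per-reaction proportions converge to p/(1 − ∏(1 − p)) — numerically
indistinguishable from the configured p whenever the vocabulary is rich
enough that empty draws are rare, which is the realistic regime.

The generator does **not** model reporting dynamics over time,
under-reporting, co-reporting correlation between PTs, or drug
co-administration; passing tests say nothing about those features of real
dashboards.

## Operating characteristics harness

`operating_characteristics` replays `simulate → screen → rule` over seeded
replicates and reports, per (drug, reaction) pair: mean estimated PRR with
its Monte-Carlo standard error, the analytic `expected_prr`, and the flag
rate with a binomial standard error; pairs with λ ≠ 1 are pooled into a
power estimate, the rest into a false-positive rate. The reference
configuration (also used by `scripts/acceptance.py`) is three drugs, an
eight-PT vocabulary at baseline p = 0.05, one injected λ = 5 pair, 20 000
reports per drug and 200 replicates — large enough that the injected pair's
PRR estimator is effectively unbiased at the harness's standard errors, and
small enough to run in about half a minute on one CPU.

## Synthetic IHC cohort generator

Per grade, the configured (mean, SD) describes the distribution of a case's
marker burden. One latent value per (case, marker) is drawn — truncated
normal at 0 by default, or a mean/SD-matched negative binomial
(Poisson when SD² ≤ mean) — rounded to an integer and replicated across the
`n_fields` fields. An optional `field_sd` adds within-case field noise
(default 0). Two consequences worth knowing:

* With the default `field_sd = 0`, a case's ten fields are identical — a
  deliberate simplification that makes grade-level summaries converge to the
  configured (mean, SD) exactly, at the cost of realistic field-to-field
  scatter. Turn on `field_sd` for realistic-looking fields; grade-level SDs
  then inflate slightly (by field_sd²/n_fields in variance).
* Truncation at zero biases the realized mean upward when mean < ~3 SD
  (the G1 macrophage setting, 6 ± 4.24, realizes ≈6.7). The configured
  values are pre-truncation parameters; convergence tests use markers where
  the bias is nil.

Default parameters are the reference cohort's: grade sizes 45/34/22;
per-grade marker means/SDs for CD68, CD20-monoclonal and CD20-polyclonal;
per-grade serum platelet/lymphocyte/neutrophil means/SDs, carried by only
the first 4 cases per grade (`serum_n = 4`) as in the source cohort.
Histotypes are sampled from the 101-case marginal frequencies,
*independently of grade*: the source's per-histotype grade cells are
internally inconsistent (grade-I cells sum to 50 against a printed total of
45), so the grade totals row is treated as authoritative and no
histotype–grade dependence is claimed.

## Between-grade testing

The grade comparisons are unpaired: the groups are independent and of
unequal size (45 vs 34 vs 22), so a paired test is structurally impossible.
Default is Welch's t with Welch–Satterthwaite degrees of freedom; `pooled`
gives the classical equal-variance Student test. SDs use the n−1
denominator. Tests accept summary statistics (n, mean, SD) directly so
published tables can be re-analysed without raw data; the summary route is
verified against raw-vector `scipy.stats.ttest_ind` on matched inputs.
No multiplicity adjustment is applied by default (matching common practice
in small descriptive cohorts); Bonferroni and Holm are available behind a
flag. Two zero-SD groups with equal means return t = 0, p = 1; with unequal
means they are rejected as ill-posed rather than reported as p = 0.

## Numerical and degenerate-input choices

* Exact integer/rational arithmetic wherever a threshold is compared
  (PRR = 1 exclusion, percentage rounding); floats elsewhere.
* Screening uses one cross-tabulation per class rather than per-pair row
  scans; the per-pair enumeration oracle remains in the tests.
* Filtering bounds are inclusive; filters that remove everything yield an
  empty analysis set with provenance, not an error.
* All randomness flows from a single integer seed per entry point; replicate
  seeds are drawn below 2³¹ from the parent generator.

## Known limitations

* The surrogate de-duplication key cannot reproduce a manual duplicate
  review and saturates on coarse-demographic synthetic data (see above).
* Headline disproportionality values from the motivating analyses that
  depend on unpublished full 2×2 marginals cannot be recomputed from printed
  counts; the package instead exposes the printed-count worked example
  (PRR ≈ 6.40) and validates the machinery on synthetic ground truth.
* The IHC generator reproduces first- and second-moment structure per grade,
  not spatial structure (intratumoral vs. peritumoral localisation) or
  inter-marker correlation within cases.
* Confidence intervals for PRR are out of scope, as are other
  disproportionality statistics (ROR, EBGM, IC).
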