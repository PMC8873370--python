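# advesig

Disproportionality signal detection for spontaneous adverse-drug-reaction
(ADR) line listings, plus grade-association analysis of tumor-infiltrating
immune cells — two computational strands that meet in comparative oncology:
inflammatory and blood-count reactions reported under anti-HER2 monoclonal
antibodies in humans, and CD68⁺ macrophage / CD20⁺ lymphocyte infiltrates
across malignancy grades in canine mammary carcinoma.

The package is aimed at pharmacovigilance analysts and veterinary-pathology
researchers who need these computations reproducible, tested, and runnable
offline: it ships synthetic-data generators with known ground truth for both
data kinds, so every stage can be validated without access to any dashboard
or archive.

## The statistics

**Proportional Reporting Ratio.** For a drug of interest within an explicit
comparator class, reports are cross-tabulated as

|                      | reaction of interest | all other reactions |
|----------------------|:---:|:---:|
| drug of interest     |  a  |  c  |
| other drugs in class |  b  |  d  |

and

```
PRR = (a / (a + c)) / (b / (b + d))
```

A drug–reaction pair is flagged as a *signal* when PRR ≥ 2, the reaction has
at least 3 cases, and the Pearson χ² of the table is ≥ 4 (all three
thresholds configurable; PRR exactly 1 never signals). χ² is Pearson's
`N(ad − bc)² / ((a+b)(c+d)(a+c)(b+d))`, with an optional Yates continuity
correction. Degenerate comparator cells (b = 0) either raise (strict) or
receive the Haldane–Anscombe +0.5 correction, by explicit policy.

**Grade association.** Cases carry a histological grade (G1–G3) and
per-field immunostain counts (10 fields at 400×, 0.1885 mm² per field).
Per-case marker burden is the mean of its field counts; grades are compared
with two-sided two-sample t-tests — Welch (default) or pooled — computed
either from raw vectors or directly from published summary statistics
(n, mean, SD). Serum inflammation biomarkers are summarised as
NLR = neutrophils/lymphocytes and PLR = platelets/lymphocytes.

## Worked example

```python
from advesig import (ContingencyTable, compute_prr, compute_chi2,
                     evaluate_signal, reaction_share, ttest_summary)

# platelet-count-decrease reports for an antibody-drug conjugate (286 of its
# 623 blood-and-lymphatic reports) against the rest of the anti-HER2 class
t = ContingencyTable(a=286, b=327, c=337, d=4230)
prr = compute_prr(t)                      # 6.40
chi2 = compute_chi2(t)                    # 788.0
signal, why = evaluate_signal(prr, t.a, chi2)   # True, ()
share = reaction_share(286, 623)          # 45.9 (% of the SOC's reports)

# G1 vs G3 macrophage burden from published per-grade summaries
res = ttest_summary(45, 6.0, 4.24, 22, 46.5, 24.64, variant="welch")
# t = -7.65, df = 21.6, p = 1.4e-07
```

Printed output of exactly this session:

```
PRR  = 6.40
chi2 = 788.0
signal = True  (n_cases = 286)
share = 45.9%
t = -7.65, df = 21.6, p = 1.37e-07
```

Read: platelet-count decrease is reported 6.4× more prominently for this
drug than for its in-class comparators and clears every signal threshold;
it accounts for 45.9 % of the drug's blood-and-lymphatic reports. In the
canine cohort, macrophage infiltration differs strongly between the
least- and most-malignant grades.

## Command line

```sh
advesig simulate --kind pv --seed 1 --out listing.csv
advesig filter --in listing.csv --age 18-64 --sex female --years 2015:2020 --out analysis.csv
advesig screen --in analysis.csv --class "trastuzumab,pertuzumab,trastuzumab emtansine" \
               --zero-policy haldane --out signals.tsv
advesig shares --in analysis.csv --drug trastuzumab
advesig simulate --kind ihc --seed 1 --out cohort.csv
advesig ihc-summary --in cohort.csv --test welch --out ihc.tsv
advesig oc --replicates 100 --reports-per-drug 5000
advesig run --config run.yaml     # config-driven end-to-end pipeline
```

Exit codes: 0 success, 2 usage/configuration error, 3 data error. Tables
are TSV with a header comment carrying the run's configuration hash; logs go
to stderr.

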