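# Methods

This note records the statistical model behind `jaderpv`, the conventions
chosen where the field's practice is genuinely open, and what the synthetic
data can and cannot establish about behaviour on real spontaneous reports.

## The data model

A spontaneous-reporting extract is three tables keyed by an opaque case ID:
DEMO (sex, age band per patient), DRUG (drug name, involvement code,
start/end dates per drug record), REAC (preferred term, onset date, outcome
per event record). Dates are partial by design — year/month/day or
year/month, serialized `YYYY-MM-DD` / `YYYY-MM`, empty string for missing —
and unparseable values degrade to missing rather than dropping rows, because
every downstream statistic is a ratio of report counts and silently shrunken
denominators are the classic failure mode of reporting-database analyses.

Deduplication removes rows that are equal in *every* field. Public
distributions do not document a duplicate key, and any fuzzier rule
(same case + term, ignoring dates, …) silently embeds an assumption about
which of two conflicting records is real; exact equality is the only
reproducible, assumption-free reading. The merge takes the inner join of
DRUG × REAC on case ID with DEMO attached (unknown demographics when a case
is absent from DEMO) and collapses to unique (case, drug, term) triples.
Where one (case, drug) pair carries several DRUG records, the collapsed row
takes the highest causality code (suspected > interaction > concomitant >
unknown): a pair *anyone* reported as suspected must survive the
suspected-only filter. The un-collapsed DRUG table remains the source of
dosing episodes, so no date information is lost to the collapse.

The analysis data table is the suspected-only subset of these triples, and
all disproportionality denominators count triples. Unrecognized involvement
tokens map to a fourth `unknown` code — the row survives (denominators
again) but is never suspected.

## Disproportionality

For target drug D and event E the table partitions into a (D-and-E),
b (D-not-E), c (E-not-D), d (neither), and

    ROR = (a/b) / (c/d) = ad / (bc).

The interval is Woolf's log-normal approximation,
`exp(ln ROR ± z·sqrt(1/a+1/b+1/c+1/d))` with z = Φ⁻¹(0.975) ≈ 1.959964 —
the universal convention for RORs in pharmacovigilance. The test is
Fisher's exact, two-sided by the probability-mass rule (sum over tables
with fixed margins whose probability does not exceed the observed one);
`scipy.stats.fisher_exact` implements exactly this definition and the test
suite verifies it against full integer-arithmetic hypergeometric
enumeration on every table with n ≤ 30. The signal criterion is a ≥ 5
reports (inclusive) and lower CI bound strictly above 1.

Zero cells: the minimum-case screen makes a = 0 impossible in reported
rows, but c = 0 can occur for an event unique to the target drug. The
screen then applies the Haldane–Anscombe +0.5 to all four cells and flags
the row `corrected`; calling `ror()` directly with a zero cell raises,
naming the cell, because silent continuity correction is how implausible
RORs sneak into tables. Display rounding is half-up — 2 decimals for
rates/ROR/CI, 1 for percentages — with full-precision companion columns in
every output file; the signal flag is always decided on unrounded bounds.

## Time to onset

Onset days = (onset date − start of the relevant dosing episode) + 0.5.
The half-day convention gives a same-day onset 0.5 days of exposure and
removes zeros from the log-likelihood. Conventions, each switchable:

- **Year/month resolution**: day 1, not day 15. Conservative under the
  +0.5 rule (never shortens an onset to negative), and reproducible; a
  `day_of_month` parameter exposes the alternative.
- **Episode gap**: dosing records merge into one episode unless the gap
  from the last known date to the next start exceeds 365 days (leap-year
  nuance deliberately ignored); a longer gap starts a new episode and the
  *latest* episode starting on or before the onset anchors the
  calculation.
- **Eligibility**: a report enters the onset count only when the onset
  date and the anchoring drug record's start *and* end dates all resolve to
  at least year/month precision (`require_end_date=False` relaxes the end
  date requirement). Negative onsets (event before any episode) and onsets
  beyond the 730-day horizon are rejected and counted, never clamped.
- **Histogram**: 30-day bins from zero by default (bin width is a
  parameter); left-closed bins with the final bin closed on the right so a
  sample exactly at the horizon is kept.

The two-parameter Weibull is fit by maximum likelihood on the uncensored
samples: the shape score equation is solved by bracketed root-finding
(Brent), the scale follows in closed form, and 95% CIs are Wald intervals
in (log α, log β) from the numerically evaluated observed information,
back-transformed — with profile-likelihood intervals available as an
option, since the two disagree noticeably below n ≈ 30 and neither can
claim to be "the" convention for report data. Censoring-aware fits are out
of scope: the data are observed onsets only. Samples with n < 3 get point
summaries without intervals; an all-identical sample makes β diverge and is
returned as indeterminate with a warning. Medians and IQRs are
linear-interpolation sample quantiles, reported alongside the parametric
fit precisely because they do not depend on it.

Classification: β CI entirely below 1 → early failure (decreasing hazard);
entirely above 1 → wear-out (increasing); spanning 1 → random (roughly
constant); no CI → indeterminate. β is dimensionless, so the rule is
invariant to the time unit, which the tests check.

## Outcomes

Fatality percentage = deaths / reports with a *stated* outcome. `unclear`
is a stated category and stays in the denominator; record-level
missingness does not, and is reported separately. This is a documented
choice — reporting practice varies and the alternative (pooling missing
with unclear) changes fatality rates for sparsely documented terms.

## The synthetic generator

`generate(SimConfig)` samples cases with configured sex/age marginals,
independent per-drug exposure, and per-case event occurrence with
probability `background × Π rate-ratio(drug, event)` over the case's
drugs, capped at 1. Onset dates are the anchoring drug's start (uniform
over a 2004-04 – 2021-03 window) plus a Weibull draw rounded down to whole
days; the anchor is the exposed drug with the largest rate ratio for that
event. Outcomes are categorical per event. Dirt is injected to exercise
the cleaning stages: exact-duplicate DRUG/REAC rows (default 5% of rows),
dates degraded to year/month (default 10%), and date-less concomitant
co-medication rows (default 30% of cases). Identical (config, seed) pairs
are byte-identical.

What it deliberately does **not** emulate: reporting delays and secular
reporting trends, within-case correlation between events beyond shared
drug exposure, dose information, real drug-name vocabularies, and
non-random missingness. Tests passing on synthetic data therefore
establish the *arithmetic and inferential* correctness of the pipeline
(type-I behaviour near nominal under the null; a planted rate ratio of 5
detected essentially always at the 20,000-case scale; planted Weibull
parameters recovered within a few percent), not robustness to the biases
of real spontaneous reports — which no simulation faithful to the model
under test could.

`reference_margin_fixture()` is the complementary, fully deterministic
instrument: it reconstructs the published bevacizumab lung-toxicity
margins exactly on the target-drug side (20,399 report triples, the 29
per-term case counts summing to 1,679, the published sex/age counts) and
back-solves the other-drug event counts from the published RORs against
the full-database totals (5,273,115 triples), then scales that side down
100-fold (integer-rounded) to stay desk-sized. Consequently target-side
rates, counts and percentages reproduce the published values exactly,
while other-side quantities (RORs, CIs, p-values) are approximate — close
for common terms, loose for rare ones where integer rounding of a
scaled-down count bites. The acceptance checks assert only the exactly
reproducible quantities, plus CI arithmetic computed at the true
(unscaled) margins.

## Problem sizes

The simulation-based checks use 500 replicates of 2,000 cases for null
calibration, 100 replicates of 20,000 cases for power, 200 replicates of
n = 150 for Weibull interval coverage and n = 1,000 for point recovery —
sizes at which the asymptotics under test are expected to hold and a full
run of suite plus acceptance script completes in a few minutes on one
core.

## Known limitations

- Name normalization is whitespace/case-folding only; no MedDRA or drug
  dictionary mapping, so synonymous terms count separately.
- The exact-equality duplicate rule cannot remove true duplicates that
  differ in any field (e.g. re-reports with corrected dates).
- Woolf intervals and Wald Weibull intervals are asymptotic; both are
  known to be anti-conservative at very small counts, which is why the
  screen's minimum case count and the n ≥ 3 CI rule exist.
- No multiple-testing adjustment across screened terms: a screen over k
  terms carries k chances of a false signal, as is conventional for
  hypothesis-generating disproportionality analyses.
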