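# Methods

## Data model and deduplication

FAERS-style extracts split one safety report across six `$`-delimited
tables keyed by PRIMARYID (a report version) and CASEID (a case that may
accumulate versions). Deduplication keeps, per CASEID, the version with
the most recent FDA receipt date (FDA_DT), breaking ties by the larger
PRIMARYID. Two deliberate edge-rules:

- Only strict 8-digit `YYYYMMDD` values are treated as dates anywhere in
  the package; 4- and 6-digit partial dates count as missing. This single
  dialect rule is shared by deduplication and time-to-onset cleaning.
- A missing FDA_DT ranks below every real date, so a dated version always
  supersedes an undated one; the rule's intent is recency.

Cohort selection requires a drug row whose normalized name (trimmed,
whitespace-collapsed, case-insensitive) matches the synonym list *with
role PS*, plus at least one indication PT matching the indication list.
By default the indication row must be linked (via drug sequence number) to
a matching target-drug row; a flag relaxes this to any row in the report,
since reporting practice varies. Cases with no indication recorded are
excluded. The background comparator is every deduplicated report that does
not qualify for the cohort — the standard full-database comparator.

## Disproportionality statistics

ROR, PRR, χ² and the raw information component are implemented exactly as
conventionally printed (see README), with no continuity correction in χ².
Numerical policies:

- **Zero cells.** If any of b, c, d is zero (with a ≥ 1), 0.5 is added to
  all four cells for ROR/PRR/χ² and the result is flagged `corrected`. The
  a ≥ 3 gate always uses the raw count, so the correction can never create
  a signal out of thin air. With a = 0 the ROR/PRR point estimates are 0
  (never a signal).
- **IC credible bound.** The IC025 uses the closed-form posterior-moment
  approximation of the original BCPNN formulation: margin priors add 1 to
  each margin cell (prior totals 2) and the joint-cell prior weight is
  scaled so the prior expectation of IC is zero; IC025 = E(IC) − 2√V(IC).
  The raw IC is reported alongside so both forms are auditable.
- **Thresholds.** All five criteria are strict inequalities; "N ≥ 3" is
  read as a ≥ 3 (the joint-cell count).
- Counting is report-level: a report listing the same PT twice contributes
  one to `a`; at SOC level a report counts once per SOC regardless of how
  many of its PTs map there. PTs without a SOC mapping are returned
  explicitly, never silently dropped (MedDRA is licensed, so the PT→SOC
  map is a user-supplied two-column TSV).

The implementation is cross-checked in the test suite against exact
rational (Fraction) arithmetic on 1,000 random tables (≤1e-9 relative
error) and against a multinomial simulation showing 93–97% coverage of the
ROR's nominal 95% CI.

## Subgroup comparison

Stratified detection reuses the full joint-criteria machinery with cohort
and background both restricted to the stratum. The between-stratum model
is a 2×2 within the cohort only (stratum A with/without the PT vs stratum
B), with ROR = ad/bc, the same uncorrected χ² form, and its 1-df upper
tail as the p-value. Benjamini–Hochberg adjustment runs over the family of
PTs entering the comparison; when reproducing the shared-signal analysis
that family is the set of PTs signal-positive in both strata (an explicit,
separate filter). Orientation: stratum A is female (or monotherapy), so
ROR > 1 with adjusted p < 0.05 is direction A. Cases with missing sex are
excluded from sex comparisons. Monotherapy is defined as a single distinct
drug after collapsing target synonyms; for cohort reports this coincides
with "no concomitant medication" and the same rule extends to background
reports in stratified runs. An adjusted p of exactly 0 is clamped to the
smallest positive float for the −log₁₀ axis and flagged.

## Time-to-onset

Onset is the whole-day difference between the event date and the earliest
valid therapy-start date of the target drug (first exposure). Exclusions
are counted by reason: missing/partial start date, missing/partial event
date, and event on or before the start day (intervals ≤ 0 are excluded,
consistent with a minimum of 1 day). Spontaneous reports exist because the
event occurred, so there is no censoring model; the log-rank test and
cumulative incidence (empirical CDF per sex) operate on fully observed
times via lifelines.

The Weibull fit is maximum likelihood, written in-house because the
shape-parameter test is the analysis's centrepiece: the shape β solves the
profile score equation by Brent's method (with logsumexp-stabilized
weights), the scale α then has a closed form, and 95% CIs are Wald
intervals on (ln α, ln β) from a central-difference observed-information
matrix — positivity-respecting by construction. lifelines' WeibullFitter
serves as an independent cross-check in the tests (agreement to 1e-5).
Classification: β CI entirely below 1 → early failure (decreasing hazard),
entirely above 1 → wear-out, otherwise random. Fits require n ≥ 30. The
reported median/IQR/min/max are empirical summaries, not fitted
quantities; the fitted median α(ln 2)^(1/β) need not match the empirical
median when the data are not exactly Weibull.

## Synthetic-data generator

The generator emulates multi-table quarterly extracts with exactly known
ground truth. Per report: one primary-suspect drug (target with
probability `p_target_drug`, else one of eight background drugs), optional
concomitant drugs (role C), sex, demographics, an indication (IBD terms
for target reports), and independent Bernoulli draws for each PT in the
background vocabulary. For target reports the per-PT probability comes
from inverting the odds: q = ROR·o/(1+ROR·o) with o the background odds,
which makes the configured reporting odds ratio analytically exact; sex
multipliers act on the target-PT odds. A report with no sampled PT gets a
neutral filler reaction ("Drug ineffective") so every report carries a
REAC row. Duplicates are injected as an earlier-FDA_DT superseded version
of an existing case mirrored across all tables, so correct deduplication
provably removes exactly the injected PRIMARYID set. Onset times are a
continuous Weibull draw rounded to whole days; day-0 roundings are later
excluded by the cleaning rule (≈0.4% at the default scale). The
calibration raises an explicit error when the required target-arm event
probability is within 1e-9 of 1, where the no-event cell degenerates in
floating point.

Defaults are the study conditions where a value is reported: concomitant
rate 0.673, female share 0.548 (= 50.7/(50.7+41.8) of sex-known reports),
onset Weibull scale 912.75 d and shape 0.73, ~7.5% missing demographics.
Free choices, made once: 100k reports by default (60k in the analysis
drivers — large enough for stable per-PT counts at desk scale), a
15-term PT vocabulary with baseline rates 0.003–0.03, 25% target-drug
share, 25% missing-date rate per date field, 5% duplicate rate, and three
injected effects anchored to printed subgroup signals (an immune-mediated
PT stronger in females, a haemodynamic PT slightly stronger in males, a
sex-neutral infection).

What the generator does **not** emulate: reporting-rate drift over
calendar years, drug-drug or PT-PT correlations beyond the shared sex
effect, country- or reporter-specific behaviour, free-text narratives,
name misspellings (matching is exact by design), or a bounded onset
support (the Weibull tail occasionally exceeds the multi-decade intervals
seen in practice). Passing tests therefore demonstrate estimator and
pipeline correctness under the generating model, not robustness to the
messiness of real extracts. In particular, sex and onset are independent
in the generator, so a small log-rank p-value in any single synthetic run
is a type-I event, not a recovered effect.

## Validation experiments (simstudy / acceptance script)

- **Weibull recovery:** 50 seeds × n = 15,682 draws at scale 912.75/shape
  0.73; the ML estimates fall within the reference CIs (892.19–933.31 and
  0.72–0.74) in ≥90% of seeds, and every fit classifies as early failure.
- **ROR recovery:** single-sex extracts calibrated so a designated PT has
  true subgroup ROR 7.09 (female) or 29.33 (male), sized for ~1,000
  target-PT reports (background event rate 0.04 resp. 0.02, 35% target
  share); the full generate → ingest → stratified-detect estimate covers
  the truth with its own 95% CI in ≥90% of 50 seeds.
- **Median recovery:** onset scale calibrated so the theoretical median is
  620 days; the cleaned empirical median at n = 15,682 agrees within 2%
  (median over 5 seeds, since a single empirical median has ≈1.6% sampling
  error at this n).
- **Null calibration:** 50 seeds × 12,000 reports with no injected effects
  (size chosen for suite runtime; the type-I level under test does not
  depend on it): per-PT joint-signal false-positive rate ≤ 7% and
  between-sex FDR-significant fraction ≤ 5% + Monte-Carlo slack.

All randomness flows from a single integer seed; derived sub-seeds are
`(seed·1009 + i) mod 2³¹`.

## Known limitations

- Name matching is exact after normalization; real FAERS drug strings need
  an external synonym curation step.
- The between-stratum model adjusts for nothing; like the underlying
  statistics it measures reporting disproportionality, not causal risk.
- SOC-level results inherit whatever PT→SOC table the user supplies;
  partial maps surface unmapped PTs but the SOC denominators still count
  all cohort/background reports.
- The Weibull CIs are asymptotic Wald intervals; at n near the fitting
  minimum (30) they can undercover.
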