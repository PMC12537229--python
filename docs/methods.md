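# Methods

`pvsignal` implements a complete spontaneous-report signal-detection
pipeline of the kind used on the FDA Adverse Event Reporting System
(FAERS): ingestion and deduplication of quarterly report tables,
disproportionality analysis with four algorithms at MedDRA PT and SOC
level, multi-algorithm signal classification, descriptive reporting, and
Weibull time-to-onset modelling. Because no raw FAERS extract ships with
the package, every stage is validated against a synthetic report-database
generator whose ground truth is known by construction.

## Ingestion and deduplication

FAERS publishes '$'-delimited ASCII tables keyed by report version
(`primaryid`); one case (`caseid`) may be re-reported several times. The
pipeline follows FDA deduplication guidance: per case, keep the version
with the latest receipt date (`fda_dt`), breaking ties by the highest
`primaryid`, compared **numerically** — FAERS primaryids are numeric
strings, and lexicographic order would misorder ids of different length.
Deduplication precedes date-windowing, which precedes the primary-suspect
(PS) filter; the PS filter matches upper-cased, whitespace-collapsed drug
names exactly against a configured synonym list (substring matching is
opt-in, since free-text verbatims vary).

Dates of 8/6/4 digits carry day/month/year precision. Coarse dates are
anchored at the first day of their period for windowing only, so a report
is never dropped from the window over granularity; calendar-invalid
digit strings become missing with a warning. The window filters on
`fda_dt` (receipt), which also defines the reporting year in descriptive
tables — a product launched in Q4 of one year can therefore show a small
count for that year. Ages are converted to years by unit code
(YR×1, DEC×10, MON÷12, WK÷52.143, DY÷365.25, HR÷8766); a missing unit
with a numeric age is read as years, the dominant FAERS convention, and
results outside [0, 150] are treated as missing.

## Counting unit and 2×2 tables

The unit of analysis is the **report–reaction pair**: each distinct
(primaryid, PT) combination counts once (duplicate listings on one report
collapse), and at SOC level each PT pair contributes one count to its
SOC — a report listing two PTs of the same SOC contributes two SOC pairs.
This is the only unit under which ~2000 cases plausibly carry ~5000
analysable events, and it is declared in the run manifest. For an event
E, a = target pairs with E, b = other target pairs, c = E's pairs under
all other drugs, d = the rest; N = a+b+c+d.

## Disproportionality statistics

* **ROR** = ad/(bc), 95% CI = ROR·exp(∓1.96·se), se = √(1/a+1/b+1/c+1/d).
* **PRR** = [a/(a+b)]/[c/(c+d)] with the uncorrected Pearson χ² of the
  table (Yates correction available by flag; at the counts where the
  thresholds bite, the two are practically indistinguishable).
* **EBGM** uses the simplified relative-reporting-ratio form
  aN/[(a+b)(a+c)], with EBGM05 = EBGM·exp(−1.64·se), the lower one-sided
  95% lognormal bound. The full DuMouchel gamma–Poisson shrinkage EM is
  intentionally out of scope: at FAERS-scale counts the shrunken EBGM is
  close to the relative reporting ratio, and published Tyrvaya tables are
  numerically consistent with the simplified form (their IC equals
  log2(EBGM) row by row, e.g. log2(7.91)=2.98, log2(4.78)=2.26).
* **IC** = log2(aN/[(a+b)(a+c)]) — identically log2(EBGM) in this form.
  Two IC025 modes exist. `fixed_offset` (default) places IC025 a constant
  1.66 bits below IC, matching the uniform IC−IC025 spacing seen in
  published Tyrvaya tables irrespective of count — a spacing no
  count-dependent posterior variance can produce, so the published bound
  is evidently a fixed offset. `bate` computes IC − 1.96·sd from the
  closed-form BCPNN posterior (priors α₁=β₁=1, γ chosen for prior IC 0)
  and is the recommended mode for new analyses. The mode is recorded in
  the manifest.

Zero cells: a=0 yields a zero point estimate with undefined (NaN)
bounds, flagged rather than raised; no Haldane +0.5 correction is applied
by default (an option exists but is off).

**Thresholds.** An event is positive for an algorithm only with a ≥ 3
reports and: ROR lower CI > 1; PRR ≥ 2 with χ² ≥ 4; EBGM05 > 2;
IC025 > 0. Events are graded by the number of concordant algorithms
(0–4); 4-of-4 events are treated as adverse reactions, 2–3-of-4 as
noteworthy. These conventional cutoffs reproduce the published Tyrvaya
calls exactly: ear and labyrinth disorders 2 of 4, headache and
hypersensitivity 3 of 4, insomnia/sinusitis/dry mouth/vertigo 2 of 4, and
the respiratory/eye/product-issue SOCs 4 of 4.

## Time-to-onset

TTO = event date − earliest day-precision therapy start, in whole days.
Negative intervals are excluded (event predates therapy); same-day events
are remapped to 0.5 days rather than excluded, since discarding them
would bias against immediate reactions (sneezing on first use being the
canonical example for an intranasal agent) — the remap value is
configurable. Summaries use type-7 (linear-interpolation) quantiles.

The two-parameter Weibull f(t) = (β/α)(t/α)^{β−1}exp(−(t/α)^β) is fit by
exact maximum likelihood: the shape MLE solves the profile score
1/β + mean(log t) − Σtᵝlog t/Σtᵝ = 0 by bracketed root finding (the
bracket is expanded geometrically until the score changes sign), and the
scale follows as (mean tᵝ)^{1/β}. 95% CIs are Wald intervals on
(log α, log β) from the numerically evaluated observed information,
back-transformed — guaranteeing positive bounds; percentile bootstrap CIs
are available for small samples. No censoring model: only observed onset
times enter. Degenerate samples (all values equal, or n < 3) raise.
Failure mode: *early* if the β CI lies below 1 (decreasing hazard),
*wear-out* if above 1, *random* otherwise.

## Synthetic database

The generator emits DEMO/DRUG/REAC/THER in the dialect the reader
ingests, deterministic given the seed (byte-identical files on rerun).
Defaults mirror the published Tyrvaya reporting profile: 2178 target
reports (vs 20000 background), sex mix 74.0% F / 11.8% M, 71.2% missing
age, reporter mix 85.1% consumer / 8.6% physician / 6.0% other health
professional / 0.2% pharmacist, onset times Weibull(shape 0.60, scale
16.73 d) observable on a 125/2178 subset, receipt dates uniform over
Q4 2021–Q2 2024. Reports draw 1 + truncated-Geometric(p=1/2.4, max 10)
reactions (mean ≈ 2.3, matching ~5189 pairs per 2178 cases), each PT
sampled with replacement from the catalog weights — multiplied by the
per-PT signal multiplier for target reports and renormalised. The chance
a report contributes a pair for PT j is therefore E_k[1 − (1−p_j)^k],
and `expected_contingency` returns the exact expected 2×2 cells from
that expression; the planted "truth" for a signal is the odds ratio of
those expected cells (because of renormalisation, a multiplier m does
not equal the marginal odds ratio once other PTs are also boosted).

Duplicates: a fixed 5% share of cases (configurable) is emitted as
exactly two versions with strictly increasing primaryid and fda_dt, so
deduplication has a unique correct answer; a tie mode emits equal dates
to exercise the primaryid tie-break. Onset wiring: eligible target cases
get event_dt = start_dt + round(TTO) with a 1-day minimum, since FAERS
dates have day precision. A small fraction (1%) of target cases carries
an event date *before* therapy start to exercise the negative-interval
exclusion.

**What the generator does not emulate:** co-medication structure,
realistic country mixes, free-text drug-name noise, secular reporting
trends, and PT correlations within a report beyond the shared draw
count. Passing end-to-end tests therefore demonstrates correctness of
the pipeline's logic and calibration under a clean multinomial world,
not robustness to real FAERS messiness. One consequence worth knowing:
whole-day rounding of Weibull(0.6) onset times compresses the sub-day
tail, so the shape recovered from generated *dates* is biased somewhat
above 0.60 (≈0.7 at n=125), while fits on unrounded durations are
unbiased — parameter-recovery checks therefore use unrounded samples,
and the end-to-end check asserts the qualitative early-failure call.

## Problem sizes and numerics

Test and script problem sizes (20000-report backgrounds, 200-PT null
catalogs, 200×n=125 Weibull replicates) are chosen so the whole suite
runs in well under a minute while keeping Monte-Carlo error far from
the asserted margins. Stochastic assertions use fixed seeds and
tolerances derived from analytic or simulation standard errors (3σ
unless stated). The Weibull root-finder uses xtol 1e−12 on the shape;
the observed-information Hessian uses central differences with step
1e−5 on the log-parameters. Proportions are rounded half away from
zero at the printed precision (1 d.p.; receipt-year rows 2 d.p.) — the
only scheme consistent with the published descriptive table.

## Known limitations

* Simplified EBGM/IC forms (no shrinkage): appropriate for replication
  and for large-count screens, anticonservative for very small a
  relative to full MGPS; EBGM05's lognormal bound is likewise an
  approximation.
* No stratification (age/sex/year) and no multiple-testing adjustment,
  matching standard first-pass practice.
* No censoring in the TTO model; reports without day-precision dates
  are simply excluded, and the eligible subset is assumed representative.
* The PT→SOC map is user-supplied (a 42-term stand-in ships for tests);
  MedDRA licensing, LLT→PT coding and SMQ groupings are out of scope.
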