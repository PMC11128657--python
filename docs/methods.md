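# Methods

This note records the statistical models behind `faerspv`, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical choices a maintainer would want written
down.

## Data model and deduplication

A FAERS-style corpus is a set of *report versions*: one DEMO row per
version (keyed `primaryid`), with DRUG/REAC/THER/OUTC rows attached by
`primaryid`. Versions of the same safety report share a `caseid` and
carry increasing `caseversion` integers. The pipeline concatenates all
quarters first and then keeps, per `caseid`, the highest `caseversion`
(ties broken toward the largest `primaryid`) — the documented convention
for building a current snapshot, and the reason concatenation must happen
before deduplication: a case revised in a later quarter has to collapse
onto its latest version. Report versions without any reaction row are
unusable for a reaction-level analysis and are dropped with a count;
retained + duplicates + reaction-less always equals the number of
distinct `primaryid`s read (a conservation check the tests enforce).

Ages are normalized to years from the `age_cod` unit
(DEC×10, YR, MON/12, WK·7/365.25, DY/365.25, HR/8760); anything
unparseable, or outside [0, 130] years, becomes missing rather than an
error. Input text is decoded as UTF-8 with replacement. Dates are the
FAERS digit strings; a date is *complete* only as a valid YYYYMMDD
calendar date, otherwise year-month, year-only or invalid. Only complete
dates take part in onset arithmetic.

## Target-drug cohort

Drug names in spontaneous reports are free text. Matching first
normalizes (upper-case, whitespace collapse, salt/hydrate token
stripping), then applies the dictionary's mode. The default is
*substring* — a synonym contained anywhere in the normalized name — which
captures "BENDEKA 100MG/4ML" style entries while staying close to the
explicit synonym list; an edit-similarity mode (normalized Levenshtein,
threshold configurable in (0, 1]) is available where misspellings matter.
Substring is the default because unrestricted fuzzy matching against
short brand names produces false positives that a synonym list was meant
to avoid. One report counts once regardless of how many of its drug rows
match. The analysis cohort takes reports where the match carries the
primary-suspect (PS) role code.

### Descriptive table denominators

The demographics table is *available-case*: each category's percentages
use the category's non-missing count as denominator, and every level also
carries a percentage of the whole cohort (`pct_total`). Two deliberate
conventions: severe outcomes are one level per report, resolved by a
severity priority (Death > Life-threatening > Hospitalization >
Disability > Other), so levels sum to the number of reports with any
severe outcome; and the top-k-countries category uses the *sum of the
listed top-k counts* as its denominator, so the displayed country shares
total 100%. Percentages are `100·count/denominator` rounded half-up to
two decimals.

## Disproportionality statistics

The counting unit everywhere is the unique deduplicated report; for each
event term with at least one cohort report, the 2×2 table is (a, b, c, d)
against the full corpus, with `E = (a+b)(a+c)/N` the expected count under
row–column independence. SOC-level tables roll PTs up to their primary
SOC; a report counts once per SOC it touches.

* **ROR** `ad/bc` with log-normal 95% CI. Any zero cell triggers the
  Haldane–Anscombe +0.5 on all four cells, and the result is flagged as
  corrected. Signals are never computed for a = 0 (no table is built).
* **PRR** with the Yates-corrected Pearson χ² (scipy's
  `chi2_contingency`). Yates is the convention under which the composite
  rule PRR ≥ 2 ∧ χ² ≥ 4 ∧ n ≥ 3 was proposed; the uncorrected statistic
  is available by flag.
* **IC** `log2((a+0.5)/(E+0.5))`. This is the shrinkage estimate implied
  by a Gamma(a+0.5, E+0.5) posterior for the relative reporting rate, so
  three lower bounds are offered: the closed-form approximation
  `IC − 3.3(a+0.5)^(−1/2) − 2(a+0.5)^(−3/2)` (the default used by the
  signal criterion), the exact gamma-posterior quantile, and a
  Monte-Carlo percentile. The credible level of the quantile methods is
  configurable (2.5% or 5%): the literature's "IC05" label is ambiguous
  between the two, and the package does not guess — the default bound is
  the closed form, and the tests verify the gamma quantile against
  Monte-Carlo sampling.
* **EBGM/EB05** from the gamma-Poisson shrinker below.

The combined flag is the conjunction PRR ≥ 2, χ² ≥ 4, a ≥ 3, IC lower
bound > 0, EBGM > 2 ("at least" thresholds are ≥, the IC and EBGM bounds
strict). No multiplicity adjustment is applied: the method screens with
fixed thresholds rather than controlling a false-discovery rate, and the
docs say so rather than silently adding one. Rankings are produced twice,
by report count and by ROR CI lower bound, each with the other statistic
as tie-break, mirroring how screening tables are usually printed.

A note on monotonicity: with b, c, d held fixed, ROR and PRR increase in
a without qualification, but IC does not — as a grows comparable to the
margins, E approaches a and IC returns toward 0. The property tests
therefore assert monotonicity in the rare-event regime (a small against
b and c), which is the case/non-case operating region.

## Empirical-Bayes gamma-Poisson shrinker (MGPS)

Counts are modelled as `a ~ Poisson(λE)` with
`λ ~ w·Γ(α₁,β₁) + (1−w)·Γ(α₂,β₂)` (shape/rate). Marginally `a` is a
two-component negative-binomial mixture whose likelihood is maximized
over the five prior parameters, on log/logit scales for unconstrained
quasi-Newton optimization. Starting points are the classic DuMouchel
start, four further fixed points, and two deterministic data-adaptive
starts that place the signal component at the empirical 99th percentile
of `(a+0.5)/E` — without these, corpora containing only a handful of
truly associated pairs can trap the optimizer in a degenerate
point-mass-at-1 mode that shrinks everything to EBGM ≈ 1. A Nelder-Mead
polish runs from the best point; non-convergence on every start raises an
error that still carries the best parameters found. Components are
reported ordered by prior mean. The prior is fitted database-wide (every
drug × PT pair, a = 0 pairs included; a ≥ 1 truncation with the
conditioned likelihood is available by flag) and persisted as JSON.

The posterior is again a gamma mixture;
`EBGM = exp(Σ Qᵢ(ψ(αᵢ+a) − ln(βᵢ+E)))` and EB05 comes from root-finding
on the posterior mixture CDF (bracketed by the component quantiles,
tolerance 1e-6). Two known behaviors worth keeping in mind: on a truly
null database the maximum-likelihood prior legitimately concentrates near
λ = 1, so all EBGMs shrink to ≈ 1; and when the associated pairs all
share one true λ, the fitted signal component can be nearly degenerate
at that value, making EB05 ≈ EBGM for those pairs.

## Time-to-onset and the Weibull shape test

Onset is event date minus the *earliest complete* therapy start among
target-drug rows. Exclusions (incomplete start, incomplete event,
negative onset) are flagged per record, never silently dropped, and the
three reasons are mutually exclusive with "incomplete start" checked
first. A report contributes its onset to each SOC its reactions map to,
which is why per-SOC counts sum to more than the cohort size.

Summaries use linear-interpolation quartiles (numpy default). The
monthly histogram uses 30-day bins with month 1 covering days 0–30
inclusive and month 12 extended to day 365, so the final bin is exactly
"more than one year".

The Weibull fit is the exact two-parameter MLE via the profiled shape
equation (scale has a closed form given shape; the remaining
one-dimensional root is bracketed and solved to near machine precision),
which keeps the scale-equivariance property `α̂(kt) = k·α̂(t)` to 1e-6.
Day-resolution onsets contain exact zeros, which a continuous Weibull
density cannot carry when β < 1, so half a day — the interval midpoint of
"day 0" — is added before fitting (configurable; pass 0 for continuous
data). The shape CI is the observed-information normal approximation
(finite-difference Hessian at the MLE). Hazard classification is
CI-based: *early failure* only when the whole 95% CI for β lies below 1,
*late failure* only when it lies above, *constant* otherwise — a
conservative rule that refuses the call when the data cannot exclude a
constant hazard. The three-parameter (location-shifted) Weibull is
available behind a flag and never auto-selected. Per-SOC fits require at
least 10 included records (configurable); published per-SOC scale values
from spreadsheet tooling are not always in day units, so this package
reports α in days and leaves reconciliation with other software to the
user.

## Synthetic corpus generator

The generator emulates the *structure* of the 2017–2023 FAERS extracts:
multi-table rows keyed by report ID, revision duplicates
(`duplicate_fraction`, default 0.10, emitted as a second caseversion, in
the following quarter when several quarters are written), drug role
codes, multi-PT reports, demographic missingness, and incomplete dates
(`missing_date_fraction`, default 0.15, truncating or blanking the
therapy-start or event date). Reactions are an independent multinomial
over the bundled PT vocabulary with fixed long-tailed weights, except
injected pairs: conditional on the named drug being present (with the PS
role, for the target), the injected PT's probability is multiplied by ρ
and the distribution renormalized. For rare margins the pair's ROR
concentrates near ρ; because several PTs are drawn per report without
replacement, the realized ratio sits slightly below ρ, so tests measure
against Monte-Carlo intervals rather than ρ exactly. Onset times are
per-SOC Weibull draws (default scale 30 days, shape 0.8 — an
early-failure profile typical of infusion reactions) floored to whole
days; event date = therapy start + onset. Configurations whose ρ would
push a conditional probability past 1 are rejected before any file is
written.

Default cohort geometry: 2% of reports carry the target drug, 80% of
those as primary suspect — at the 50,000-report corpus used for
end-to-end checks this yields a cohort of roughly 800 reports, planted
pairs with a ≥ 20, and null pairs with single-digit-to-tens counts,
which is the regime the combined criterion is designed for.

Everything derives from one integer seed through a single PCG64
generator, and all set-like iteration in the generation path is sorted,
so a configuration reproduces its files byte-identically across
processes and platforms. The ground-truth manifest (report/duplicate
counts, per-PT cohort counts, true onsets, planted ρ values) is
regenerable from the configuration alone.

What the generator does **not** emulate: real drug co-prescription
correlation, free-text verbatim reaction strings and their coding noise,
reporting-volume trends over time, and country- or reporter-specific
reporting cultures. Passing the end-to-end tests therefore shows the
pipeline's arithmetic and decision logic are right under known truth —
it does not validate performance on real FAERS data, where duplicate
detection and name matching are substantially harder.

## MedDRA stand-in

MedDRA is licensed and cannot be shipped. The bundled hierarchy is a
synthetic stand-in — real PT and SOC names from a haematology-drug
safety profile, invented HLT/HLGT labels — sufficient for tests and
synthetic corpora; real analyses should point `hierarchy_path` /
`smq_path` at licensed TSV exports (`pt, hlt, hlgt, soc,
primary_soc_flag` and `smq, pt, scope`). Multiaxial PTs resolve to their
primary SOC; LLT-level coding is out of scope.

## Problem sizes

The test suite exercises the pipeline on a 3,000-report two-quarter
fixture corpus (duplicate fraction 0.2, 10% target share so per-SOC fits
have data) and one 50,000-report end-to-end corpus with four planted
pairs at ρ = 5; oracle comparisons use 1,000 random 2×2 tables, 10⁶-draw
Monte-Carlo posteriors, and 200-replicate Weibull recovery at n = 300.
The acceptance script refits Weibull samples at the published per-SOC
sizes (n = 665 and 621). These sizes were chosen to put every statistic
in its intended operating regime while keeping runs reproducible on a
laptop.

## Known limitations

* Disproportionality measures are screening statistics; nothing here
  estimates incidence or establishes causality.
* No stratified or regression-adjusted variants (age/sex strata,
  LASSO-type methods) — out of scope by design.
* The deduplication key is the documented caseid/caseversion convention;
  probabilistic duplicate detection (same patient reported twice under
  different caseids) is not attempted.
* The Weibull analysis treats onsets as fully observed; censoring and
  competing risks are not modelled.
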