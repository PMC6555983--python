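# Methods

`mrcc-claims` reconstructs first- and second-line (1L/2L) targeted-therapy
episodes for metastatic renal cell carcinoma (mRCC) from administrative
claims, and computes the descriptive and inferential outputs a
pharmacoepidemiology study of this design reports: an eligibility
cascade with attrition, Kaplan-Meier treatment-duration and
time-to-second-line (TT2T) endpoints, 1L→2L flow, washout-adjusted
adverse-event (AE) incidence per 100 person-years (PY), AE onset
latency, annual initiation trends, and logistic models of treatment
choice. Because the claims databases such analyses run on are
proprietary, the package ships a synthetic claims generator with full
ground truth; every analysis stage has a recovery test against it.

## The claims model

Diagnosis and procedure codes are stored normalized: uppercased, no
decimal point. Code sets are prefix lists — `C64` realizes the
`C64.xx` wildcard — matched by `str.startswith`. The drug catalog
holds the eight 1L study agents plus interferon-alfa (IFN-α):

| agent | class | route | coverage per claim |
|---|---|---|---|
| sunitinib, sorafenib, pazopanib, axitinib | TK/VEGF | oral | days supply |
| bevacizumab (± IFN-α) | TK/VEGF | IV | 14-day cycle |
| everolimus | mTOR | oral | days supply |
| temsirolimus | mTOR | IV | 7-day cycle |
| aldesleukin (IL-2) | IL-2 | IV | 14-day cycle |

IV coverage uses the labeled dosing interval (configurable; the values
above follow US label cadence). IFN-α exists only as bevacizumab's
combination partner and never anchors an index date alone. Dates are
ISO-8601 in files; all intervals are closed on both ends, and "month"
quantities are fixed day counts (3 months = 90 days, 6 months = 180
days) so every rule is exactly testable.

## Eligibility cascade

Applied in order, with attrition recorded after each step:

1. **Diagnosis**: ≥2 kidney-cancer claims (ICD-9 189.0 / ICD-10 C64.xx)
   on separate dates ≥30 days apart. The diagnosis window is the index
   window padded by 184 days before and 273 after, reflecting a total
   study period that brackets the index period.
2. **Index claim**: the *first-ever* claim for a study agent must fall
   within 30 days before the first kidney-cancer claim and no later than
   the index-period end (default 2011-01-01 … 2015-12-31). Three
   refinements: (a) bevacizumab and IFN-α first claims within 30 days of
   each other form one combination regimen indexed at the earlier claim;
   (b) two different agents within 5 days of the index exclude the
   patient; (c) a different agent starting within 30 days of the index
   *with a subsequent refill* replaces the index (the new agent's first
   claim becomes the index date). The 5-day check is evaluated at the
   original index; the replacement rule is iterated to a fixpoint with a
   bound of 5. A candidate without a refill neither replaces the index
   nor (being inside the 30-day switch window) starts a second line.
3. **Age** ≥18 at index, from the enrollment record's birth year.
4. **Continuous enrollment**: one normalized span (adjacent spans merge
   when gapless in whole days) covering index ±180 days. Follow-up ends
   at that span's end.
5. **Exclusions**: any claim for a TCC-indicated agent (configurable
   list) from 30 days pre-index through follow-up end; ≥2 baseline
   claims for one non-RCC primary cancer in the 180 days up to index.
   The other-primary code sets deliberately omit lung, bone, brain and
   liver, the sites RCC commonly seeds — codes there are read as
   metastases, not second primaries.

Baseline covariates (comorbidity flags, metastatic-site flags,
nephrectomy, and the modified Deyo-Charlson index) are evaluated over
the 180 days up to and including index. The DCCI here removes the
malignancy/metastasis categories (every cohort member would score
them), keeps the standard Deyo weights and hierarchy rules
(complicated diabetes over diabetes, moderate/severe over mild liver
disease), and ships abbreviated ICD-9/10 prefix lists suitable for
synthetic data. Demographics are read from the enrollment span
covering the index date.

## Line-of-therapy rules

Coverage of a claim ends at `date + days_supply` (oral) or `date +
cycle_length` (IV). Consecutive claims of the index regimen are one
episode while the *uncovered* gap — next claim date minus previous
coverage end — is ≤90 days; coverage is not stockpiled (an early refill
restarts coverage at its own date + supply; an `extend` mode is a
documented non-default alternative we did not implement because the
conservative rule is the common convention). The combination regimen
stitches the union of both partners' claims.

A second line starts at the earlier of: the first claim for a
different agent strictly more than 30 days after index, or a restart of
the index agent after a gap >90 days. Events:

* **1L duration** — event at episode end when a 2L exists or when the
  episode ends more than 90 days before enrollment end; otherwise
  censored at enrollment end. If a 2L starts before coverage ends
  (add-on/overlap), the episode is truncated at the switch date — the
  duration clock stops at the switch, consistent with its definition.
* **TT2T** — event at the 2L start; non-switchers censored at
  min(episode end, enrollment end).

## Survival, incidence, inference

Kaplan-Meier estimation is delegated to `lifelines`
(`KaplanMeierFitter`); the package adds Greenwood variance bookkeeping,
months conversion (days/30.4375), and median 95% CIs by inverting the
pointwise exponential-Greenwood (log(−log)) band at 0.5 — the
Brookmeyer-Crowley-style interval that clinical software conventionally
reports. "Not reached" propagates as ∞ and prints as `NR`. Tests
verify the estimator against a brute-force product-limit oracle at
1e−12 and check 93-97% empirical coverage of the median CI over 500
exponential replicates (n=200).

AE incidence: for each AE, patients with a matching claim in the
pre-index washout — 365 days for chronic conditions (hypertension,
hypotension, hepatitis, thyroid disorders, renal insufficiency, adrenal
insufficiency, myasthenia gravis), 30 days otherwise — are removed from
numerator *and* denominator for that AE only. The risk window runs
from index (day-0 onsets count) through 30 days after the 1L episode
end, capped at enrollment end. Person-years accrue to first onset or
window end; IR = 100 × events / PY with the exact Garwood CI
(χ²(α/2, 2k)/2, χ²(1−α/2, 2k+2)/2 scaled by 100/PY) — small counts make
normal approximations useless here. Onset latency is median and Q1-Q3
in days with linear-interpolation (type-7) quartiles; a single onset
yields degenerate quartiles (x, x, x). Strata are all patients, drug
class (TK/VEGF vs mTOR; IL-2 belongs to neither class but stays in the
route/agent/all denominators), route, and agent. The bundled AE code
sets are synthetic defaults for the generator, not a vetted clinical
list; real analyses must supply their own.

Treatment-choice models: Welch t tests for continuous covariates and
chi-square tests for categorical ones (Fisher's exact for 2×2 tables
with any expected cell <5; multi-level categoricals such as index year
always use chi-square since the exact test is defined for 2×2), a
P<0.2 selection gate with age, sex and index year always forced in, and
a maximum-likelihood logistic fit with Wald CIs on exponentiated
coefficients. Reference levels: TK/VEGF class and oral route as
reference outcomes; index year 2015, sex M, retiree, commercial
insurance as reference covariate levels; DCCI enters continuous (a
categorical encoding is a one-line config change). Non-convergence,
perfect separation, or a |coefficient| >15 raise `SeparationError`
rather than returning silently unstable estimates. No multiplicity
correction is applied in the screen — the gate is intentionally
liberal.

## The synthetic generator

Defaults emulate the target claims population: index years 2011-2015
(weights ≈ .215/.21/.21/.185/.18), mTOR-class assignment through a
logistic model (intercept −2.4; CHF +0.9, diabetes −0.45, bone mets
+0.45, liver mets +0.5, index year 2011 +0.55 / 2012 +0.5 on the
log-odds) giving ≈12% mTOR and ≈88% TK/VEGF with sunitinib and
pazopanib dominant, 0.6% IL-2, 3% of bevacizumab as the IFN-α
combination; per-agent exponential treatment durations with medians of
2.8-12 months; 30-day oral fills with uniform 0-10-day refill slack; IV
administration at the labeled cycle; latent switch propensity 52.8%
(10% of switches are index-agent restarts after a >90-day gap);
enrollment lead-in ≥380 days (so the 365-day washout look-back is
always observable) and follow-up 180 days + an exponential with mean
330. Comorbidity and metastasis prevalences, age (N(62, 11²), 30-90),
and sex mix follow the emulated cohort's composition. Per-AE onsets
are exponential waiting times at class-specific hazards on the scale of
the observed incidence rates, generated independently per AE (competing
risks ignored, matching the per-AE incidence computation); pre-existing
disease claims land inside the 30-day window with probability 0.3,
else in the 31-365-day band, so both washout widths are exercised.

Two properties are by construction, and they are what the exact
recovery tests lean on: refill gaps never exceed the 90-day stitch
threshold, and a different-agent 2L start is placed at
`max(1L coverage end + delay, index + 31)`, so the >30-day switch rule
never misclassifies it. Ground truth (index, agent, 1L end, 2L
start/agent, AE onsets, covariates, assignment log-odds) is recorded
from the *realized* claims, so truncation at disenrollment is truthful.
Determinism: each patient has an independent stream
`default_rng([seed, ordinal])`; a fixed seed reproduces the bundle byte
for byte, independent of generation order. A covariates-only fast path
(`simulate_cohort_covariates`) replays the same per-patient streams
without claims realization for coefficient-recovery studies.

What the generator does **not** emulate — and hence what passing tests
do not show about real data: claim-line noise (miscoded or missing
claims, truncated fills), dose changes, stockpiled refills, mortality
(death is unobservable in these claims), correlated AE processes,
NDC/HCPCS→agent mapping (a hook exists; the generator emits agent
names), and informative disenrollment. Recovery being exact here means
the rules are implemented losslessly, not that real-world line
assignment is error-free.

## Numerical and design choices

* Integer day arithmetic throughout the rules; no time zones; ties in
  KM handled events-before-censorings (lifelines convention).
* The index-determination tie-break when two agents share the earliest
  first-claim date is lexicographic after the date; such patients are
  then 5-day-excluded anyway.
* `incidence_rate` refuses zero total person-years; empty latency
  strata are omitted from the table rather than printed as 0, and true
  day-0 onsets are reported as 0.
* Attrition monotonicity and event-table conservation (|cohort| =
  |duration events| = |TT2T events| = flow-table total) are asserted
  inside the library, not only in tests.
* Problem sizes in the test suite: exact line-of-therapy recovery at
  n=5,000; incidence oracle equivalence at n=1,000 with rate recovery
  at n=5,000; KM median recovery at n=10,000 with 500×200 coverage
  replicates; 100×5,000 replicates for coefficient recovery through the
  covariates-only fast path; 20-seed structural-invariant sweeps at
  n=150. These sizes give Monte-Carlo error comfortably inside the
  asserted tolerances.

## Known limitations

* The observed 2L share in generated cohorts (≈36-37%) is below the
  52.8% latent switch propensity because switches scheduled after
  disenrollment are unobservable — the same mechanism that depresses
  switch counts in real claims.
* The cross-sectional trend cohort reuses the same builder; by default
  it keeps the 6-month post-index enrollment requirement
  (`require_post_enrollment=False` relaxes it).
* Fisher's exact test is restricted to 2×2 tables; rare multi-level
  covariates therefore rely on the chi-square approximation.
* The bundled AE/TCC/nephrectomy/other-primary code lists are
  synthetic defaults; results on real data are only as good as the
  code sets supplied.
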