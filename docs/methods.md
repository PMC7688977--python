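# Methods

## Cohort derivation

A registry extract has one row per tumour. The analysis cohort keeps
squamous-cell oral-cavity tumours — topography C00.3–5, C02.*, C03.*, C04.*,
C05.0/.8/.9, C06.* and morphology 8050–8089 — diagnosed 2004–2016, surgically
treated, first primaries only (at most one tumour per patient; when several
qualify, the earliest diagnosis is kept, earlier input row breaking exact
date ties). Topography matching is prefix-based at three characters for C02,
C03, C04 and C06 and exact at four characters for C00.x and C05.x, so the
soft palate (C05.1) is excluded while every tongue subsite is included.
Unparseable codes reject the record into the exclusion log (patient id →
first failed rule); they never crash a run.

Survival runs from diagnosis to death or last follow-up, administratively
censored at the information horizon (default 2019-01-31): deaths recorded
after the horizon count as censored at the horizon, whatever the vital
status field says later. Time is days/365.25, rounded half-up to one
decimal year. The one-decimal grain is a deliberate trade: it caps the
number of distinct event times (K ≤ ~150 for 15 years of follow-up), which
bounds the size of every federated payload and the per-iteration cost, at
the price of heavy ties — which the Breslow likelihood absorbs. Rounding
half-up and the 365.25-day year are this package's choices (conventions
differ across registries); both are visible in `round_years` and recorded in
output metadata via the fit JSON.

Covariates are binned as the models use them: age <60 / 60–69 / ≥70, period
of diagnosis 2004–2007 / 2008–2011 / 2012–2016, stage group early (I–II) /
advanced (III–IVC) / unknown, anatomical location in five groups, grade in
four (unknown kept as an explicit level, never dropped or imputed — the
published models report hazard ratios for it), treatment surgery-only vs
surgery plus adjuvant radio/chemotherapy. Hospital volume is the count of
retained oral-cavity surgeries at the patient's treating centre in the
diagnosis year, categorized <50 / 50–99 / ≥100; it is computed within one
registry only, from post-filter records (the definition is surgeries for
this disease, which is what survives the filter).

The full multivariable specification dummy-codes country + eight factors
against reference levels into exactly 18 columns.

## Federated estimation

The server/node layer is simulated in-process: nodes are actors holding a
private DataFrame and a registry of operations; the only objects crossing
the boundary are `Task` (operation name + parameter payload) and
`TaskResult` (aggregates). A socket transport could replace the in-process
dispatch behind the same contract. Authentication is reduced to a static
token per node; encryption and deployment are out of scope.

The Cox fit proceeds in rounds: (1) union of per-site distinct event times —
the shared grid is itself a cross-site disclosure (rounded event times), a
requirement of the per-event-time decomposition, and is documented as such;
(2) federated column means, used only to center the dummy columns before
exponentiation (the partial likelihood, score, information and estimates are
invariant to the shift; centering only conditions the exponentials);
(3) Newton–Raphson from β = 0, one aggregate round per iteration; (4) a
final round at the estimate for the log-likelihood, a stationarity check and
the covariance = inverse observed information.

Numerical choices:

* **Stopping rule** — the default criterion is the hazard-ratio-sum rule,
  |Σ e^{β_new} − Σ e^{β_old}| < 10⁻⁸; a max|Δβ| < tol criterion is
  selectable (`FitOptions.criterion`). The two agree at any interior
  stationary point; correctness is asserted against an independent oracle,
  not the stopping metric. Well-conditioned fits converge in ≈5 iterations.
* **Ties** — Breslow only. Censored subjects at an event time stay in the
  risk set at that time.
* **No step-halving by default** — plain Newton–Raphson as the method
  prescribes; divergence is an error carrying the iteration trace
  (`FitOptions.step_halving` enables a log-likelihood-guarded fallback).
* **Singular information** — raised with the most collinear column pair
  named, rather than silently regularized.
* **Event times as integers** — tenths of a year are stored as ints, so grid
  membership is exact and no float-equality traps exist.
* **95% intervals** use z = 1.959964.
* d_k and s_k are β-independent and computed once per fit (recomputing them
  every round would be mathematically identical).

Site aggregates are computed in O(n·p² + K·p²) per round by bucketing
subjects into grid intervals and accumulating suffix sums from the latest
time down, so the n = 20,000, p = 18 fits the tests run take seconds.

The interaction likelihood-ratio test is joint over the whole country×factor
block ((levels−1) columns against the single country dummy), one factor at a
time, with all other main effects retained as adjustment — the reduced model
is the full main-effects model. Per-country hazard-ratio tables come from
one joint model per factor (not a saturated model); "unknown" levels
participate in interactions like any other level.

## Synthetic registries

The generator defines the study conditions for everything that cannot run
on real data. Defaults: per-registry sizes 7,766 (NL) and 33,867 (TW);
per-country categorical marginals proportional to the published per-registry
level counts (stage at its seven-level detail, so the early/advanced
grouping is derivable); true log hazard ratios set to moderate,
registry-realistic multivariable effects (e.g. age ≥70 → log 2.40, advanced
stage → log 2.19, adjuvant treatment → log 1.40, country → log 1.06);
exponential baseline hazard 0.05/year in the reference cell; censoring time
uniform on (2.1, 15.1) years, the follow-up potential implied by uniform
2004–2016 accrual against a 2019-01-31 cutoff. Times are rounded to one
decimal exactly as the cohort pipeline rounds them, so ties are realistic.
With these conditions roughly 60% of subjects die in follow-up, and the
empirical censoring fraction matches the closed-form value
E[(e^{−λa} − e^{−λb})/(λ(b−a))] within Monte-Carlo error (tested).

Covariates are drawn independently per variable — only marginals are
published, so the generator does not emulate the registries' joint
distributions, calendar trends, or within-hospital correlation. Passing
tests therefore demonstrate correctness of the *algorithms* under a
proportional-hazards world with realistic marginals, ties and censoring;
they say nothing about how well a proportional-hazards model describes the
real registries (the method's own proportionality diagnostics are a known
gap, see Limitations).

Two entry points with different jobs:

* `generate_cohort` — analysis-ready rows, the fast path for estimator
  studies (oracle equivalence, recovery, coverage, LRT calibration), where
  `known_truth` alignment matters. Hospital volume is an ordinary drawn
  categorical here.
* `generate_registry` — dated raw tables for the full pipeline. Hospital
  identifiers are constructed so realized per-hospital-year surgery counts
  land inside volume strata: records of each year are grouped greedily into
  hospital-years sized for the stratum with the largest remaining
  country-level deficit (hospital-year size bounds 1–49 / 50–99 / 100–250).
  Because annual volume is a per-year count, a small cohort spread over 13
  diagnosis years cannot realize a ≥100 stratum in every year; the greedy
  deficit scheme concentrates the high-volume stratum in as many years as
  the numbers allow, absorbs leftovers into an existing legal hospital-year,
  and raises when a requested stratum is arithmetically infeasible (e.g. a
  pure-≥100 profile with under 100 surgeries a year). Survival is generated
  from the *realized* volume category, so the pipeline-derived cohort is
  consistent with the generating truth. Contaminant records, each violating
  exactly one inclusion rule, are appended on request to exercise the
  exclusion log.

## Verification design

The estimator is checked against two independent routes: a brute-force
centralized Breslow fit (boolean-mask risk-set sums, quasi-Newton
optimization, then Newton polishing on brute-force derivatives — a different
decomposition and a different solver than the package's), and R's
`survival::coxph(ties = "breslow")` invoked through Rscript on one fixture.
Agreement is required to 10⁻⁶ on coefficients and standard errors;
partition invariance (1–5 sites) to 10⁻⁹. Note the installed lifelines
release handles ties by Efron's method, so it is deliberately *not* used as
the Breslow reference.

Simulation problem sizes were chosen as the package's own test conditions:
oracle equivalence at n = 2,000 with the full 18-column design; recovery at
n = 20,000; CI coverage pooled over 3 coefficients × 200 replicates at
n = 600 (600 intervals put the Monte-Carlo standard error of the coverage
estimate near 0.9%, comfortably inside the 93–97% acceptance band); LRT null
calibration over 500 replicates at n = 2,000 with a compact
country + age-group base model.

## Limitations

* Proportional-hazards diagnostics (e.g. Schoenfeld residuals) are not
  implemented — a known gap of the method itself, not just this package.
* Efron ties, stratified baselines, time-varying covariates and penalization
  are out of scope.
* The shared event-time grid discloses rounded event times across sites;
  deployments needing stronger guarantees would coarsen the grid further or
  add noise, at a cost in estimator exactness.
* The simulated federation exercises the aggregation contract, not network
  failure modes, stragglers, or adversarial nodes.
* No multiplicity adjustment is applied across the five interaction tests.
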