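# Methods

## The scientific problem

The package compares first-primary cancer incidence in persons with type 1
diabetes (diabetes diagnosed below age 40) against the *total* background
population of five countries (Australia, Denmark, Finland, Scotland,
Sweden), each observed over its own study window.  Because the prevalence
of type 1 diabetes is below 1%, the total population is an acceptable
comparator.  The quantity of interest is the hazard ratio (HR) of cancer
associated with type 1 diabetes, overall and as a function of diabetes
duration.

## The rate model

Events and person-years are classified by country `n`, sex, 1-year age
class `a`, 1-year calendar period `p`, birth cohort `c = p − a` and
diabetes duration band `d` (cut at 0, 1, 2, 5, 10, 15, 30 years; general
population is the reference level).  The incidence rate in a cell is
modelled as

    log λ_napcd = f_n(a) + g_n(p) + h_n(c) + δ_d

fitted by Poisson regression with the cell event count as outcome and
log person-years as offset, separately by sex (and by site, where a site
is analysed).  `f`, `g`, `h` are per-country natural cubic splines.
exp(δ) is a proportional-hazards contrast between the T1D and population
rate surfaces — the smooth-model generalisation of a classical
standardised incidence ratio (SIR/SMR), which `smr_oracle` computes from
empirical rates as an independent cross-check.

### Knots

Interior knots are placed at event-weighted quantiles so the number of
cases between consecutive knots is equal (±1; events tied exactly at a
knot count toward the lower interval).  Defaults: 5 interior knots per
timescale per country, computed from all events (population + T1D pooled;
configurable to either source alone).  When a timescale would average
fewer than 50 events per inter-knot interval the interior count is halved
until the threshold is met, which keeps desk-scale fits stable.  Boundary
knots sit at the observed extremes and the spline is linear beyond them
(natural-spline tail behaviour), guarding against instability where
population rates are sparse.

### APC identifiability

Age, period and cohort satisfy `c = p − a`, so the three spline blocks
share one linear redundancy per country.  The default constraint
detrends the cohort basis — each country's cohort columns are projected
(person-years-weighted) orthogonal to {1, c} — absorbing the drift into
the period term.  The alternative `detrend-period` constraint does the
reverse.  Both constrained designs span the same model space, so fitted
rates are identical and δ, a within-stratum contrast, is invariant to the
choice (verified to < 1e-6 in the tests); the constraint used is recorded
on the fitted design.

### Estimation and inference

Fitting is iteratively reweighted least squares (statsmodels GLM,
Poisson family), converged when the relative deviance change is below
1e-8, at most 100 iterations; the covariance is the inverse Fisher
information.  Wald 95% CIs use z = Φ⁻¹(0.975) on the log scale; nested
model comparisons (per-country HR heterogeneity, df = countries − 1 per
level; age-at-diagnosis interaction over bands <30 / 30–35 / 35–40,
df = 2) use likelihood-ratio chi-square tests.  Zero-event cells stay in
the likelihood; zero person-year cells are dropped (their offset is
undefined).  A δ level whose person-time carries no events is flagged as
separated and its CI limit is reported as infinite.  No overdispersion
correction is applied (pure Poisson), and no multiple-testing adjustment
is made; reports carry the number of comparisons instead.

## Follow-up splitting

Each person enters at the later of study start and diabetes diagnosis
(persons with a cancer before entry are excluded upstream) and is split
at every age-year birthday, calendar-year boundary and duration cut, so
every segment lies in exactly one cell of every timescale; duration is
evaluated at the segment start.  All intervals are half-open [t0, t1).
Two censoring variants are implemented:

* **all_sites** — follow-up ends at the first cancer of any site, death
  or study end; used for all-cancer and non-sex-specific analyses.
* **site_specific** — follow-up runs to death or study end, ignoring the
  cancer date, so one person-time table serves every site; the event is
  attached to the segment containing its date.  `overestimation_check`
  quantifies the person-time this overstates (about 1% in the default
  synthetic cohort, mirroring the <5% reported for the registries).

Conventions: time is continuous decimal years (1 year = 365.25 days);
an event exactly on a cell boundary belongs to the cell starting there,
except an event that terminates follow-up exactly at exit, which is
counted in the final segment (the cell in which the person-time was
accrued); cohort is the label difference `c = p − a` (Lexis triangles are
not distinguished); follow-up is capped at age 90 by default (the cohort
is young; the cap avoids empty-tail instability).  Month-precision input
dates are imputed to day 15.  Persons lacking a diagnosis date (prevalent
cases in registers that record only incident onsets) get duration level
`unknown`: they contribute to the binary-T1D analysis but are dropped
from the duration analysis.

Person-time conservation is exact (segment lengths telescope), and
refining any break set leaves all aggregates unchanged; both are tested,
including against an independent quarter-day-stepping oracle.

## Synthetic registry generator

No registry data are deposited, so the generator emulates both inputs
with known ground truth:

* **Population tables** — person-years per (country, sex, age, period)
  cell from a gently declining age pyramid, with case counts drawn
  Poisson from a smooth Gompertz-type surface: log rate linear in age
  (slope ~0.03–0.045/yr) with a mild log-linear period drift.  The cell
  rate is the surface at the cell midpoint and is piecewise constant.
* **T1D cohort** — onset age ~ 40·Beta(2, 3.5) (mean ≈ 14.5, strictly
  below 40); diagnosis date uniform over (study start − lookback, study
  end); entry at max(study start, diagnosis); Gompertz mortality
  (μ0 = 8e-5, slope 0.08/yr, independent of cancer — only the censoring
  structure matters); cancer times drawn by inverse-CDF sampling from the
  piecewise-exponential hazard `population cell rate × duration-band
  multiplier`, with segments cut at every age-year, period-year and band
  boundary so the hazard is exactly constant within segments.  Prevalent
  cases in Denmark and Australia have the recorded diagnosis date
  withheld by default.

Because simulated hazards are exactly the cell-level rates the model
sees, the generator is an exact oracle: the fitted δ estimates the
configured multiplier with no discretisation bias.  The default duration
profile (2.3, 1.6, 1.3, 1.15, 1, 1, 1 across the seven bands) mimics the
observed shape of a strong first-year excess — ascertainment around the
diabetes diagnosis — declining to unity.

What the generator does *not* emulate: realistic national demography and
register sizes, competing-risk structure between cancer and death,
second primaries, site-coding error, or secular changes in registration
practice.  Passing recovery tests therefore demonstrates correctness of
the machinery under the stated model, not robustness to real-registry
artefacts.

### Desk-scale study configurations

The five-country defaults (windows AU 2000–2008, DK 1995–2012,
FI 1972–2010, SC 1995–2011, SE 1987–2012) are retained in `SimConfig`,
but recovery studies run on two named desk-scale designs, chosen once:

* `desk_binary_config` — two registers (DK, SE), windows 2000–2010, one
  sex, one site, 28,000 persons, diagnosis lookback 25 years; baseline
  rates scaled so a replicate carries roughly 500 T1D cancer events —
  the event count, not the cohort size, drives the precision of δ, so a
  desk-scale run reproduces the sampling behaviour of a full registry
  analysis at equal case counts.
* `desk_duration_config` — two registers (FI, SE), windows 2000–2013,
  40,000 persons, lookback 35 years (populating the 30+ band), flatter
  age slope so the first post-diagnosis year — spent at young ages —
  retains enough hazard to make the first band estimable (~30 events).

Recovery studies use 20 replicates each; with a correct model and ~500
events, the 95% CI covers the truth in about 19/20 replicates and the
first-vs-last band contrast exceeds z = 1.96 in essentially all.

## Duration analysis in the presence of prevalent cases

Withheld diagnosis dates remove person-time from the duration analysis
only; in the real data about 85% of T1D cancer cases had a verifiable
diagnosis date, and the package's table checks recompute that share from
the shipped counts.

## Site eligibility

Duration terms are only fitted for sites with at least 200 T1D cancer
cases in each sex (a sex-specific site is judged on its single count),
with kidney cancer included regardless, reflecting its established
association with type 2 diabetes.

## Known limitations

* The APC constraint makes `f`, `g`, `h` individually non-identifiable
  (only their sum and δ are); fitted spline blocks should not be
  interpreted in isolation.
* Wald CIs and LR tests rely on large-sample Poisson theory; with very
  sparse duration bands the separation flag, not the CI, is the honest
  summary.
* The published table is transcribed from a digit-concatenated source;
  one row (multiple myeloma, men) and the footnote-a person-year totals
  are internally inconsistent in print and are flagged, not repaired.
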