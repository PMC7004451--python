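# Methods

## Study design being emulated

The package targets the analytic core of an unmatched, population-based
case-control study of congenital heart defects: mothers are sampled on
outcome status, exposures are reconstructed retrospectively from ambient
monitoring networks over the critical embryonic window for cardiogenesis,
and the scientific question is whether extreme heat modifies the
PM2.5-defect association. Real data of this kind are restricted-access, so
every stage is exercised on synthetic data with a known generative truth;
the package's empirical claims are the operating characteristics computed by
the test suite and `scripts/acceptance.py`, not any substantive estimate.

## Exposure construction

**Conception and window.** Conception = estimated delivery date − 266 days
(38 postconceptional weeks, the standard clinical convention; source data
report EDD and gestational age but no formula, so the offset is fixed and
documented, with `conception_from_delivery` as an alternative mode using the
recorded gestational age). Week *k* covers postconceptional days
7(k−1)+1..7k, so weeks 3-8 are days 15-56 — 42 days. This indexing is stated
explicitly because off-by-seven errors are the dominant failure mode in
window arithmetic; the suite asserts the 42-day length and shift
equivariance as properties.

**Spatial linkage.** Great-circle (haversine, R = 6371 km) nearest-neighbour
linkage: PM2.5 monitors capped at 50 km (beyond that the subject is retained
with missing PM fields and an exclusion reason), weather stations uncapped.
Exact distance ties break to the lexicographically smallest site id for
determinism. One residence per subject; residential mobility is out of
scope.

**Window means and the PM2.5 cut.** Window-mean PM2.5 requires at least 28
of the 42 days observed (two-thirds coverage; monitor series are the sparse
source and no standard missing-data rule exists for them, so the default is
conservative and configurable). The dew-point mean requires only 1 day,
since station series are effectively complete. The PM2.5 threshold is the
80th percentile of window means among controls only — so adding or removing
case rows never moves it (asserted as a property) — using the linear
order-statistic interpolation at h = (n−1)p + 1 (numpy's default); `pm_high`
is *strictly above* the threshold, ties classed low. The dew-point
confounder enters models as a single linear term; no functional form beyond
linearity is claimed.

## Extreme heat events

Thresholds are percentiles of the station's Tmax distribution computed
separately per season (MAM/JJA/SON/DJF) and year; DJF belongs to the January
year. Canonical definitions: ≥ 2 consecutive days strictly above the 95th
percentile (EHE95) or ≥ 3 above the 90th (EHE90); arbitrary (q, min_run)
pairs are allowed for exploration. Runs do not cross season boundaries (the
threshold itself changes there) and are broken by missing days — a run
cannot be certified across unobserved days — and by any day at or below
threshold. A season-year with fewer than 10 observed days has no threshold
and is skipped with a logged warning. A pregnancy window is EHE-exposed if
at least one event day overlaps it (any-overlap rule: the exposure is the
heat experienced, which occurs on each event day). Note the two canonical
definitions are not nested: a 2-day extreme spike is an EHE95 event but not
an EHE90 event (asserted with a counterexample in the suite). Detection is
validated exactly against an O(n²) oracle that tests every candidate span
for the maximal-run property.

## Statistical models

All models are unconditional logistic regressions fit by Newton-type
maximum likelihood (statsmodels), complete-case, with the adjustment set
{maternal age (≤19 / 20-34 / ≥35, ref 20-34), education (<12y / ≥12y, ref
≥12y), race/ethnicity (4 levels, ref NH-white), window-mean dew point}; the
full-population model additionally adjusts for an indicator of any
critical-window day in spring or summer. Warm-season subpopulations (any
day, entire window, any summer day) are row filters, and models are run per
heat definition — both exposure scales for every cell. Dropped-row counts
are reported per model. Convergence: relative log-likelihood change < 1e-8,
≤ 100 iterations; fits with non-finite or extreme coefficients (|β| > 30,
the separation signature) are flagged non-converged, and every downstream
summary refuses flagged fits rather than propagating silently. A 4-level
cross-classification with an empty cell is flagged; the fit is still
attempted and the cell's failure is recorded in the results table's status
column.

**Multiplicative scale.** The product-term LRT uses χ²(1) with α = 0.1 — the
conventional, more liberal level for interaction tests, where power is the
binding constraint. Stratum ORs come from the one fitted model:
OR(P | H=1) = exp(β_P + β_PH) with variance var(β_P) + var(β_PH) +
2 cov(β_P, β_PH); the suite verifies this equals a refit with the heat
stratum recoded. All OR intervals are Wald.

**Additive scale.** RERI = OR₁₁ − OR₁₀ − OR₀₁ + 1, computed exactly from the
joint-model coefficients. Two intervals:

* *delta method*: gradient (−OR₁₀, −OR₀₁, OR₁₁) against the coefficient
  covariance; cheap, used as the asymptotic cross-check.
* *likelihood-based*: endpoints r solve 2(ℓ̂ − ℓ_profile(r)) = χ²₁ quantile
  (3.8415 at 95%), where ℓ_profile maximizes the constrained likelihood with
  b₁₁ eliminated via b₁₁ = log(e^{b₁₀} + e^{b₀₁} + r − 1) (infeasible
  regions handled by a smooth penalty). The search expands a bracket outward
  from the point estimate in steps of the delta-interval half-width, then
  bisects until the profile deviance matches the critical value within
  1e-3. A side with no bracket raises an error — never a silent fallback to
  the delta interval. The published description of the likelihood-based
  interval is not algorithmic, so this profile-deviance construction is the
  package's faithful generic implementation of "likelihood-based".

The suite checks the defining deviance property at the returned endpoints
with an independent derivative-free constrained optimizer, and checks
delta/profile agreement (< 10% relative width difference) at large n.

## Synthetic data

The generator reproduces the features downstream code is sensitive to:

* **Weather** — Tmax = single-sinusoid seasonal mean (default base 15 °C,
  amplitude 12 °C, peak at day-of-year 196 ≈ mid-July) plus a stationary
  AR(1) anomaly (lag-1 ρ = 0.7, innovation SD 3 °C), chosen as the simplest
  structure producing realistic multi-day percentile-exceedance runs; the
  suite verifies the empirical lag-1 autocorrelation at 10,000 days. Dew
  point = Tmax − 8 °C plus independent noise.
* **PM2.5** — seasonal mean (default 12 µg/m³, amplitude 3) times a mean-one
  log-normal factor (σ = 0.4), with days missing completely at random
  (default 10%).
* **Subjects** — residences uniform in a box; delivery dates uniform over
  the study window so conceptions span all seasons; covariates drawn
  independently from marginals loosely matching a US birth cohort, with an
  optional hook shifting residence by covariate for confounding experiments.
* **Outcomes** — Bernoulli from the logistic truth (intercept, main-effect
  and interaction log-odds, mild covariate effects); case-control sampling
  is outcome-dependent without replacement and unmatched, which biases only
  the intercept.

`simulate_analytic_table` draws the analytic table directly (Bernoulli
exposures, here P(high PM)=0.2, P(EHE)=0.35, nested warm-season flags) for
the replicated simulation studies, skipping the spatial machinery for speed.
What the generator does *not* emulate: real monitor-network geometry,
spatially correlated exposure fields, exposure misclassification by
distance, residential mobility, and outcome-group heterogeneity. Passing
tests therefore certify the pipeline's arithmetic and the estimators'
calibration under correct specification — not robustness to those realities.

## Simulation-study sizes

Chosen as the package's standard desk-scale settings: type-I error from
1,000 replicates of 1,500 cases / 1,500 controls (binomial 99% band ±0.024
around 0.10); profile-CI coverage from 500 replicates of 2,000 / 2,000
(±0.025 around 0.95); parameter recovery on a 200,000-subject cohort with
true stratum ORs 1.0 / 1.6. The coverage truth RERI = 0.5 is realized as
OR₁₀ = 1.5, OR₀₁ = 1.2, OR₁₁ = 2.2; only the RERI value itself is pinned by
the design, the split across categories being an arbitrary realistic choice.
All replicate seeds descend from one `SeedSequence`, so results are
bit-reproducible for a given seed.

## Known limitations

Wald (not likelihood-ratio) intervals for single ORs; no attributable
proportion or synergy index; no matched designs, GEE or site random effects;
no multiple-testing adjustment (matching the analytic tradition the package
follows, where the many cells are interpreted with caution rather than
corrected); percentile-threshold EHEs only (no heat-index or
warning-system definitions); thresholds are per station, not pooled across a
study center.
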