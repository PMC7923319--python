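# Methods

This note records the models, conventions and numerical choices behind
`afmap`, in the spirit of a statistical appendix: what each stage assumes,
which defaults were chosen where a convention was genuinely open, and what
the synthetic data can and cannot establish.

## Synthetic registry generator

The generator produces the data the estimators assume, so that downstream
stages are testable end-to-end without restricted register access.

**Geography.** A rook-adjacency rectangular lattice with coordinates at cell
centres (projected km). The default 7 × 14 lattice gives 98 regions — the
same count as the Danish municipal division the pipeline is shaped around —
with 175 border edges. Arbitrary geographies (points + adjacency list +
extra ferry/bridge edges for islands) are accepted everywhere; the only
requirement is a connected graph after merging the extra edges.

**Region effects.** An IID component u_i ~ N(0, 1/τ_u) and an intrinsic CAR
component v with density ∝ exp(−τ_v/2 Σ_{i~j}(v_i − v_j)²). v is sampled by
eigendecomposition of the graph Laplacian restricted to its positive
eigenspace — the standard device for sampling an intrinsic GMRF — which
makes the draw exactly sum-to-zero (recentred to remove numerical drift;
|Σv_i| < 1e−8 is asserted in tests). Defaults τ_u = 100, τ_v = 50 make
residual IRRs span roughly 0.8–1.35, a realistic order for national
disease-mapping studies; this is illustrative, not a claim about any real
geography.

**Persons.** Sex is balanced; ages at the window start follow a coarse adult
age pyramid (68% aged 25–60, 17% 60–70, 9% 70–80, 6% 80+). A latent
socioeconomic score z_p ~ N(gradient · x̃_region, 1) drives income
(rank-monotone in z with small yearly noise), education probabilities and
the hypertension-prescription propensity; the west→east gradient (default
0.6 SD across the map) is what makes socioeconomic adjustment visibly move
residual IRRs in the confounding tests. A configurable fraction of yearly
education codes is blanked to "missing"/"unknown" to exercise imputation.
Most persons hold one lifelong address; 8% move once within the window.

**Events.** The AF hazard is piecewise-constant over calendar-year ×
age-group × address pieces:
rate = exp(baseline + β'x + u_region + v_region) per person-year, with
default covariate effects of register-epidemiology magnitude (male 1.25;
age 5.8/13/28 vs 30–59; income quintiles 1.40/1.28/1.16/1.08 vs highest;
education 1.20/1.08 vs longest; single 1.18). Event times are drawn exactly
by inversion of the piecewise cumulative hazard; death (age-graded rates)
and emigration (flat 0.003/PY) are independent competing censoring
processes drawn the same way. The earliest event wins; an AF date equal to
a death date is an AF death and counts as a case. A second, much faster
simulator draws Poisson counts per region-stratum directly from the same
linear predictor; person-level and count-level routes agree within Monte
Carlo error (tested at 50,000 persons).

**What the generator does not emulate:** true municipality shapes and
populations, register coding artefacts (diagnosis-code changes, left
truncation at register start), secular trends in the hazard, migration
between more than two addresses, and household structure. Passing tests
therefore demonstrate correctness of the estimators under the stated model,
not robustness to real-register messiness.

## Cohort construction

* **Eligibility and censoring.** Entry at max(study start, 30th birthday,
  start of recorded residence); exit at the earliest of first AF, death,
  emigration, study end. Prevalent cases (AF before entry) are excluded;
  no re-entry. Same-day ties resolve AF > death > emigration.
* **Day counting.** The exit day contributes follow-up: follow-up is the
  inclusive day range [entry, exit], and all splitting partitions
  [entry, exit + 1 day). Durations are exact calendar-day counts;
  person-years = days/365.25. Conservation (Σ cell days = Σ follow-up days,
  Σ cell cases = incident cases) holds exactly and is asserted as integer
  arithmetic.
* **Age groups.** Half-open [30,60), [60,70), [70,80), [80,∞), switching on
  the calendar birthday itself (Feb 29 → Mar 1 off leap years). Calendar
  anniversaries rather than a literal 365.25-day year keep the cut points
  aligned with dates; fractional ages elsewhere use 365.25-day years.
* **Income quintiles.** Within calendar year × age band (<65/≥65 on Jan 1)
  × sex, using the income registered for the previous year (the one-year
  offset). Ranks map to quintiles with group sizes differing by at most
  one; tied incomes all take the lowest quintile of their tied block (a
  deterministic rule; the alternative of splitting ties proportionally
  changes nothing downstream but breaks reproducibility across sort
  orders). Strata under 5 persons cannot support quintiles and fall back to
  the middle group with a warning; persons with no registered previous-year
  income rank lowest.
* **Education.** "unknown" → elementary (lowest); "missing" → previous
  year's value, else the following year's. A fully missing history becomes
  elementary with a warning, and persons can optionally be dropped instead
  (the misclassification sensitivity analysis).
* **Mid-year moves.** Person-time is allocated to addresses by exact period
  overlap (pieces are additionally cut at address changes). A yearly
  residence register would allocate whole years instead; at the default 8%
  mover rate the difference is negligible but the convention is stated here
  because it is not forced by anything upstream.

## Rates and the inequality test

Point estimates are exact; intervals use the log-normal approximation
ir·exp(±1.96/√cases) for more than 5 cases and the exact Poisson (Garwood)
interval otherwise — the conventional register-epidemiology pairing. The
IRR interval uses SE(log IRR) = √(1/c₁ + 1/c₂). The Wald test for a change
in inequality is applied on the log-IRR scale (the standard parameterization
for ratio contrasts; the natural-scale alternative differs negligibly at
these SEs). Yearly series always pool cases and person-years for the
overall row rather than averaging stratum rates. Simulation checks: the
log-normal interval covers the truth in ≈95% of draws at counts ≥ 20, and
the Wald test rejects at ≈5% under the null.

## Spatial scan

Distances are planar Euclidean on projected km coordinates (the synthetic
geography is generated already projected). Candidate windows per centre are
the concentric circles at the sorted inter-point distances, with membership
defined by ≤ radius; duplicate radii collapse to a single candidate so no
window is counted twice, and the all-points window is geometrically valid
but never scored (it has no outside population). Only high-risk windows
score (LLR set to 0 when the inside rate does not exceed the outside rate),
matching a one-sided search for high-incidence clusters. The four window
presets (5%, 10%, 5 km, 10 km) run as separate configurations.

The Monte Carlo engine exploits that the Bernoulli LLR depends only on
(window size, cases inside): a lookup table turns each replicate into a
cumulative sum plus a gather, executed in a compiled (numba) kernel with a
pure-numpy fallback; both paths are tested for equality, and the candidate
maximum is tested against brute-force circle enumeration on small instances.
p-values live on the grid k/(n_reps+1), so 999 replications floor at 0.001.

Secondary clusters are reported when their centre is not inside any more
significant cluster's circle (centre-in-circle, not circle-overlap: heavily
overlapping circles can legitimately co-occur in stratified maps, and the
centre rule is the one that reproduces that behaviour). The pipeline scans
all cases plus a seeded subsample of non-cases when the cohort exceeds the
configured point budget (default 4,000); the Bernoulli model conditions on
the realized case/control totals, so down-sampling controls costs power but
not validity.

## BYM model and sampler

The piecewise exponential likelihood is a Poisson regression on person-time
cells with log person-years as offset. Cells are collapsed to sufficient
statistics per (region × covariate pattern) before sampling — exact for
this likelihood and the main reason fits take seconds. Calendar year is not
a fixed effect (the mapped five-year window is treated as homogeneous).
Treatment coding with references female, age 30–59, highest income
quintile, longest education, living with partner.

Sampler blocks per sweep:

1. **β**: per-coordinate random-walk Metropolis against the full
   likelihood plus the N(0, 1/0.001) prior; indicator columns make each
   coordinate's likelihood delta a masked sum.
2. **u**: one vectorized elementwise Metropolis update (regions are
   conditionally independent given v and β), then the conjugate draw
   τ_u ~ Gamma(a + n/2, b + Σu²/2).
3. **v**: elementwise Metropolis by graph-colour blocks (a colour class is
   an independent set, so its sites update in parallel against the CAR
   prior term −τ_v/2[m_i(v'² − v²) − 2(Σ_{j~i}v_j)(v' − v)], which equals
   the closed-form full conditional N(neighbour mean, 1/(τ_v m_i)) — both
   identities are unit-tested). After the pass, v is recentred to sum to
   zero with the shift absorbed into the intercept, and
   τ_v ~ Gamma(a + (n−1)/2, b + ½Σ_{i~j}(v_i − v_j)²) (rank n−1 for a
   connected graph).

Proposal scales adapt per site/coordinate during burn-in by Robbins–Monro
(step t^−0.6) toward 0.44 acceptance. The intercept initializes at
log(total cases / total person-years); everything else at zero. The
log-gamma(a, b) hyperprior on the log-precision is implemented as
Gamma(a, b) on the precision — the convention in which the defaults
(1, 0.0005) and the sensitivity settings (1, 0.05), (1, 0.000005) are
stated.

**Diagnostics.** Split-R̂ over chains for every fixed effect and both
log-precisions; `converged` means max R̂ < 1.05, and a fit with all R̂ > 1.2
carries a failure flag and a warning rather than an exception. Default run
length is 4 chains × 10,000 iterations (burn-in 5,000, thin 5) for
production-style fits; the test-suite and acceptance fits use 2 chains ×
1,500–2,500 iterations, which parameter-recovery simulations show is
sufficient for well-identified fixed effects at these problem sizes.

**Outputs.** Residual IRRs exp(u_i + v_i) summarized by posterior mean and
central 95% credible interval, flagged significant when the interval
excludes 1. DIC = D̄ + p_D with D(θ) the full Poisson deviance (including
the log y! term) and θ̄ the posterior mean on the linear-predictor scale;
p_D = D̄ − D(θ̄). DIC values are comparable only between models fitted to
the same cell collapse (the BYM/IID pairs reported together). The fraction
of spatial variation is the posterior mean of
var(v)/(var(u) + var(v)) using empirical across-region variances per draw
(a precision-based alternative exists; the empirical-variance definition is
the one implemented, and no published value of this quantity is claimed
reproducible). Note the usual BYM caveat: only u + v is well identified by
the likelihood, so the fraction is prior-sensitive in small data and tends
toward the structured component when τ_u is weakly identified.

## Problem sizes

Simulation-based checks run at sizes chosen to make their Monte Carlo bands
meaningful while keeping the whole suite in minutes: scan type-I-error
calibration at N = 400 points, 40 cases, 999 replications × 200 simulations
(band [0.02, 0.08]); BYM recovery at 98 regions × 2 sexes × 2,000
person-years per cell over 50 replicate fits; DIC ordering over 20
replicates per regime; person-time conservation at 10,000 persons; the
acceptance script regenerates a 40,000-person registry. The brute-force
scan oracle covers 500 instances of up to 12 points.

## Known limitations

* The intrinsic CAR is improper; inference relies on the sum-to-zero
  constraint, and the spatial-fraction summary inherits the u/v
  identifiability weakness noted above.
* At desk-scale case counts (≈10 cases per region) residual-IRR intervals
  are wide and few or no regions reach significance — the expected
  behaviour of a correctly shrinking hierarchical model, not a defect; the
  planted-effect tests use larger exposures to verify recovery.
* The scan engine holds the full inter-point distance matrix (O(N²)
  memory), which is why the pipeline subsamples controls beyond the point
  budget.
* No age standardization (rates are crude, by design), no space–time or
  elliptic scan windows, no Poisson-model scan variant, and no
  INLA-style deterministic approximation.
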