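# Methods

This note records the models behind `crvsddm`, the conventions and
defaults that were genuinely open choices, what the synthetic
generators do and do not emulate, and the known limitations.

## Death distribution methods

### Model and assumptions

Both families of methods treat the population as closed to migration
with death-registration completeness `C` constant above a minimum adult
age (default 15) and census coverage constant across ages within each
census (`k1`, `k2`). Neither assumption is testable from the two-census
data themselves; the age-trim sweep is the sensitivity instrument.

**GGB.** The balance identity says that the rate of entry into the open
age segment `x+` (persons turning exact age `x`, per person-year lived
above `x`) equals the segment's growth rate plus its death rate. With
registered deaths `D* = C·D` and census coverages `k1, k2`, the
observed coordinates

    y(x) = entry_rate(x) − r(x+),    x(x) = D*(x+) / PY(x+)

lie on a line with slope `√(k1·k2)/C` and intercept `δ = ln(k1/k2)/t`.
We report `C = 1/slope` (completeness relative to geometric-mean census
coverage) and `rel_coverage = exp(δ·t)` as the estimate of `k1/k2`.

**SEG.** The Bennett–Horiuchi identity reconstructs the flow of persons
turning exact age `x` from future deaths discounted by growth. The
discrete recursion, from the open age `A` downward, is

    N̂(x) = N̂(x+5)·exp(5·r₅(x)) + d(x)·exp(2.5·r₅(x))
    N̂(A) = d(A+)·[exp(r(A+)·ê) − (r(A+)·ê)²/6]

with `d(x)` annualized registered deaths in `[x, x+5)`, `r₅(x)` the
per-group intercensal growth rate, and `ê` the life expectancy at the
open age. Completeness is the arithmetic mean (median optional) of
`N̂(x)/N(x)` over the window's exact ages, where `N(x)` is the census
birthday flow `(₅N₍ₓ₋₅₎ + ₅Nₓ)/10` on geometric-mean counts.

**GGB–SEG.** The second census is multiplied by the GGB `rel_coverage`
(equivalently the first may be divided; configurable), the intercensal
inputs recomputed, and SEG re-run. This removes the differential-
coverage bias that plain SEG cannot absorb.

### Discretization conventions

* Growth rates `r(x+) = ln(N2(x+)/N1(x+))/t`; person-years
  `PY(x+) = t·√(N1(x+)·N2(x+))`; cumulation runs through the open
  interval inclusive.
* The birthday flow at exact age `x` is the classical
  `(₅N₍ₓ₋₅₎ + ₅Nₓ)/10` interpolation. It is undefined at the open age,
  so GGB points and SEG ratios run over `x = window_low … window_high−5`
  (13 points on the full 15–80 window).
* SEG ratios are evaluated at exact ages rather than converted back to
  five-year group counts: trapezoidal group conversion introduces a
  convexity bias of several percent at ages 75+, whereas the exact-age
  ratio is exactly 1 in a stationary, completely registered population.
* The GGB line is fitted by ordinary least squares by default; a total
  (orthogonal) least-squares option is provided because the DDM
  literature is split on the choice. On noise-free scenarios the two
  agree to machine precision.
* Degenerate fits (< 3 points, or a non-positive slope) report `C` as
  NaN and are flagged, never clipped; completeness estimates above 1
  are reported as-is.

### Open-interval closure for SEG

`ê` defaults to a data-driven fixed point: starting from the unadjusted
open-group death rate, `ê = Ĉ/M_unadj(A+)` and `Ĉ` (the SEG ratio mean)
are iterated to self-consistency — equivalent to a constant-hazard tail
at the *adjusted* open-age rate. For GGB–SEG the iteration is seeded at
the GGB completeness. A constant `open_closure_e` bypasses the
iteration; because the data-driven `ê` responds to the death scale when
`r ≠ 0`, the exact-linearity property of the recursion is stated (and
tested) with the closure held fixed. At `r = 0` the closure has no
influence at all.

### Trim sweep

Windows are every contiguous run of at least `min_groups` (default 8)
adjacent five-year groups with start ≥ 15 and end ≤ 80. Thirteen
candidate groups yield 21 windows; the `mean (min–max)` of the
per-window estimates is the reported sensitivity interval. An exclusion
list allows reproducing any published subset of windows.

### Adjusted rates

`M(x) = D*(x)/(C·PY(x))` with per-group `PY(x) = t·√(N1(x)·N2(x))`.
The three completeness values (min, mean, max) give a band of adjusted
life tables.

## Abridged life tables

Standard recursion with `q = n·M/(1 + (n−a)·M)` clipped to [0, 1],
`a = n/2` for closed intervals (adult ages dominate every use in this
package and no empirical `a` schedule is available from grouped
register data), and the open interval closed by `L = l/M`, i.e.
`e(open) = 1/M(open)` — a constant-hazard tail. Intervals are half-open
`[x, x+5)`; `l`, `T`, `e` are indexed by interval start; radix 100,000.
These closure choices affect the *level* of e₁₅ at old ages but cancel
to first order in the female−male difference when applied symmetrically
— which is how the package uses them. No old-age misreporting
correction is applied.

## Survey-based direct estimation

### Sibling histories

Real DHS-style files frequently blank the birth/death date variables;
dates are rebuilt from integer recall fields with a midpoint
convention: `death = interview − (years_since_death + 0.5)`,
`birth = death − (age_at_death + 0.5)` (living siblings:
`birth = interview − (current_age + 0.5)`). The +0.5 makes the uniform
rounding error of completed-years fields mean-zero; explicit dates are
never overwritten, and dead siblings with neither dates nor the recall
pair are dropped with a count.

Exposure is split exactly across five-year age cells as age advances,
over half-open periods `[start, end)`; the estimate is restricted to
ages 15–49 because sibling reports above age 50 are increasingly
selected and misstated. ₃₅q₁₅ is `1 − Π(1 − qᵢ)` over the seven cells.
Uncertainty is a respondent-level percentile bootstrap (default 200
replicates, seeded): whole respondents are resampled so within-sibship
correlation is preserved. Across repeated simulated surveys the 95%
interval covers the truth slightly below nominal (~93% in repeated
runs, reflecting percentile-bootstrap narrowness and the smearing of
the imputation conventions), comfortably above the 90% the acceptance
check requires. No correction is applied for sibship-size selection.

Surveys whose respondent weight column is more than 50% missing are
refused (the threshold is strict: exactly 50% is retained); the
missing fraction is always reported.

### Household deaths

Deaths and person-years are tabulated by sex and five-year age group
over the `window` (default 5) years before the survey date, the
mid-period label being `survey − window/2`. Member birth dates are
reconstructed with the same midpoint convention. Life-table summaries
(e₁₅, the sex gap) require positive exposure through the open age and
error otherwise; ₃₅q₁₅ needs only the seven adult cells.

## Synthetic generators

The DDM generator builds a stable population `N(a) ∝ e^{−ra}·l(a)` with
a Gompertz hazard `μ(x) = α·e^{βx}` (defaults α = 3·10⁻⁴, β = 0.068:
₃₅q₁₅ ≈ 0.11, e₁₅ ≈ 58 — mid-transition Latin American levels), applies
census coverages `k1, k2` and completeness `c`, and defines the *true*
intercensal deaths from the same discrete growth-balance identity the
estimators use, with the open-segment flow taken from the exact stable
density. This makes the GGB coordinates exactly collinear (residuals at
machine precision) in the deterministic closed case, so every deviation
measured in recovery tests is attributable to the estimator under
study, not to quadrature mismatch. Deaths are expected counts by
default; a Poisson switch adds sampling noise, a per-age net-migration
schedule and an age-varying-completeness slope deliberately violate the
method assumptions for negative-control tests (migration measurably
breaks SEG recovery).

The survey generators draw death ages from a supplied life table
(uniform within five-year intervals, exponential beyond the open age —
consistent with `a = n/2`) and render the files with the integer-field
pathologies the estimators must handle. They emulate sampling noise and
recall rounding; they do **not** emulate sibling omission, duplicate
listings, heaped age misstatement, correlated mortality within
sibships, or informative weights — so passing recovery tests certifies
the estimation arithmetic, not robustness to those real-data defects.

Study conditions used by the tests and the acceptance script: factorial
recovery grid c ∈ {0.5, 0.7, 0.9} × r ∈ {0, 0.01, 0.02} × k2/k1 ∈
{1.0, 0.95} with k1 = 1 (completeness in a DDM is only ever defined
relative to census coverage); sibling coverage experiment of 50 surveys
× 10,000 respondents with 200 bootstrap replicates; household-rate
recovery on a 250,000-household roster with ages 10–50, sized so the
thinnest adult cell holds several hundred expected deaths (a
power-analysis choice made before running the check); two-sex
end-to-end scenario with a true e₁₅ gap of ≈ 3.0 years and completeness
0.84 (female) / 0.80 (male).

## Known limitations

* No migration-adjusted DDM variant; the migration switch exists only
  as a negative control.
* No automatic "optimal" trim selection; the sweep reports all windows.
* The registry comparison ships published annual totals only; it does
  not ingest raw register microdata dialects.
* Percentile-bootstrap intervals are slightly anti-conservative for the
  product statistic ₃₅q₁₅ at DHS-scale sample sizes.
* The constant-hazard open-interval closure understates old-age
  survival for steep Gompertz schedules; use a finer grid (higher open
  age) when levels, not sex differences, are the target.
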