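# Methods

This note records the modelling choices behind `potatosim`: the
simulation scheme, the estimation procedures, what the synthetic-data
generator does and does not emulate, and the numerical conventions.

## Simulation scheme

The simulator is a daily LINTUL loop run under potential-production
assumptions (no water, nutrient or frost limitation; biotic stress only
via the explicit epidemic modifier):

1. **Thermal time.** Daily increment `max(0, (Tmax+Tmin)/2 − Tb)`
   accumulated from crop emergence.  The base temperature `Tb` is not
   fixed by the source field study; the common potato convention of
   2 °C is the default and is configurable on `CropParameters`.  The
   clock origin defaults to the emergence day (emergence dates are
   observed separately from canopy milestones) and can be set to sowing.
2. **Canopy.** Beta growth function of thermal time.  The function is
   undefined past `te`; cover is held at `Wmax` from `te` until an
   optional senescence onset day, after which it declines linearly to
   zero at maturity.  By default no senescence is applied (the
   maintenance phase observed in the field runs essentially to
   maturity).  Outputs are clamped to `[0, Wmax]` against floating-point
   overshoot at the endpoints.
3. **Radiation.** PAR is taken as 50% of total solar radiation
   (`par_fraction`, configurable), applied **once**: `IPAR = Σ 0.5 · SR ·
   W`.  A double application of the 0.5 factor (PAR conversion and then
   again inside the interception sum) would be dimensionally possible
   but makes the study's fitted RUE values (2.6–5.5 g·MJ⁻¹) inconsistent
   with LINTUL norms, so the single conversion is adopted.
4. **Biomass and tubers.** Total dry biomass is `RUE × IPAR`
   (exactly — the identity is asserted in tests).  Tuber dry mass is the
   Gompertz harvest index times cumulative biomass (the dynamic
   harvest-index formulation), not the integral of a partition-rate
   derivative; this matches the harvest-index definition
   (tuber/whole-plant dry mass) directly.
5. **Fresh yield.** `tuber_dm / dry_matter_fraction × 0.01` (g·m⁻² →
   t·ha⁻¹).  The tuber dry-matter fraction is not reported by the study;
   the default is 0.20, typical for table potato, and fresh yield scales
   inversely with it — override it when cultivar-specific values exist.

The printed Gompertz form in the source material is typographically
garbled; the canonical parameterization `A·exp(−exp(−(t−Tu)/b))` is
used because it makes `Tu` the maximum-rate time exactly as the
parameter table's legend states, and the fitted `b` values
(150–473 °C·d) are only plausible as thermal-time scales, not as rate
constants.

## Monthly climate handling

When only monthly climate summaries exist, they are disaggregated:
each day of a month carries the month's mean Tmax/Tmin/SR, and the
monthly rainfall total is split uniformly so per-month re-summation is
exact.  Months are positional (no calendar), with caller-supplied day
counts (default 30).  The diurnal range is computed as Tmax − Tmin per
month; the printed range row of the source climate table is internally
inconsistent with its own Tmax/Tmin rows in two cells and is treated as
reference data, not input.  No within-month interpolation is applied —
a smooth interpolant would inject structure the data do not contain.

## Parameter estimation

* Nonlinear fits (beta canopy, Gompertz harvest index, logistic yield
  curve) use trust-region least squares with parameter tolerance 1e-10
  and at most 500 function evaluations.  The beta fit is parameterized
  as `(Wmax, tm, te−tm)` so `tm < te` holds by construction; `A` and
  `Wmax` are bounded in `(0, 1]`.  Initialization is data-driven
  (maximum observed value; maximum finite-difference rate for the
  rate-peak parameters; span/5 for `b`); when the data-driven start
  fails, five deterministically jittered restarts are tried and the
  lowest-RSS solution kept.  Convergence is reported honestly in the
  result; degenerate inputs (all-zero harvest indices, shapes
  incompatible with a rising sigmoid) are flagged as non-converged
  rather than fitted.
* RUE is the slope of total dry biomass on cumulative IPAR, through the
  origin (zero interception implies zero biomass); an intercept mode
  exists for diagnostics.  Standard errors come from ordinary least
  squares.
* The day of 1% canopy cover is found by fitting a quadratic to the
  early-season observations (up to the first cover maximum) and taking
  the smallest real root of `cover(day) = 0.01` inside the observed
  span.
* All fitters sort observations internally, so results are invariant to
  input row order.  Canopy fitting accepts thermal time or calendar
  days on the x-axis; thermal time is the default.

## Yield-gap arithmetic

Seasonal potential is the unweighted mean over genotypes.  Gap tables
round the seasonal mean potential to its reporting precision (1
decimal, configurable, `None` for full precision) before subtracting
the actual yield, so reported gap + actual = reported potential exactly
— the convention under which the study's own printed decomposition is
internally consistent.  Actual yields are survey inputs; a negative gap
is returned but warned about.

## Late-blight analysis

AUDPC is the midpoint-rule integral of severity over time, invariant to
the time origin (only differences enter).  The disease index used in
yield regressions is AUDPC normalized by (span × 100) — the AUDPC of a
permanently fully-infected canopy — giving a [0, 1] predictor; raw
AUDPC is available via a flag.  Final yields for the control comparison
use the logistic asymptote `K` when the fit converged, else the last
observed point.  The logistic rate is constrained positive; a fit with
R² < 0.5 is flagged non-converged (the threshold is a pragmatic
shape-violation detector, documented here because any such cut is a
judgment call).

## Synthetic-data generator

The generator emulates the study's field protocol with known truth:

* **Weather**: monthly climate disaggregated to days; optional daily
  jitter is re-centered within each month so monthly mean temperatures
  and radiation are preserved exactly, and rainfall is redistributed by
  a Dirichlet draw conserving the monthly total.
* **Observations** every 10 days (the field cadence was 10–15 days)
  from emergence to maturity.  Noise levels are **date-level errors of
  replicate means**, because each protocol observation aggregates many
  subsamples: canopy cover is the mean of ~60 segmented photographs
  (sd 0.01), harvest index comes from a 12-plant destructive sample
  (sd 0.015), biomass totals are replicate-plot means (CV 5%,
  log-normal), severity is a visual score (sd 2% absolute).  All are
  configurable.
* **Epidemics**: the uncontrolled treatment gets a logistic severity
  curve (onset defaulting to 60% through the growth window, matching a
  mid-bulking outbreak); its yield effect is modelled as loss of light
  interception — green cover is scaled by `(1 − severity/100)` — i.e.
  the epidemic terminates the growth cycle early.  The controlled
  treatment is capped at 5% severity with a delayed onset.
* Identical configurations produce byte-identical output files.

What the generator does **not** emulate: spatial block structure and
plot-to-plot correlation, measurement-date irregularity, weather
autocorrelation within months, cultivar-specific dry-matter fractions,
and any disease mechanism other than defoliation.  Recovery tests on
these data therefore demonstrate estimator correctness under the
assumed error structure, not robustness to real-world model error.

### Recovery accuracy at the default conditions

Noise-free trials round-trip all seven parameters (`Wmax, tm, te, A,
Tu, b, RUE`) to ≤1e-5 %.  At the default noise and cadence, 20-seed
median relative errors are ≲5% for five of the seven parameters; `tm`
and `b` fluctuate around the 5% line (typically 4–8% depending on the
seed set).  This is an information limit, not an optimizer defect: the
fitted solutions have lower RSS than the truth, and with a 10-day
cadence the canopy rise around `tm ≈ 243 °C·d` is sampled only every
~138 °C·d.  In absolute terms the median `tm` error is 15–20 °C·d —
about one day of thermal time.

## Simulated potential yields and ranking

Daily weather underlying the study's own simulations is unavailable, so
simulated yields here use the monthly climates at 30 d/month and the
observed phenology; they reproduce the reported yields in magnitude and
largely in rank (autumn: exactly — C88 > YS505 > YS401; early spring:
top genotype correct).  The reported spring ordering (Yunshu 505 above
Yunshu 401) is **not** reproduced under any defensible configuration of
this scheme: Yunshu 401's fitted RUE (5.5 vs 4.4 g·MJ⁻¹) dominates all
compensating canopy/partition differences (≤10%).  The spring yields
are pinned as regression values (144.8 / 123.7 / 122.0 t/ha for
YS401 / YS505 / C88) rather than forced toward the reported order.

## Known limitations

* Potential production only: no water/N/frost stress response, no CO₂.
* Monthly disaggregation flattens within-month weather variability;
  simulated yields from monthly climates are smooth upper-bound
  approximations of what daily records would give.
* The logistic "non-convergence" flag and the multi-start jitter are
  heuristics with fixed internal seeds; they are deterministic but not
  adaptive.
* AUDPC treats severity linearly between readings; sparse late-epidemic
  sampling underestimates fast outbreaks.
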