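# Methods

## Model and assumptions

`rivermetab` estimates daily, reach-averaged stream metabolism from the diel
dissolved-oxygen (O2) curve measured at a single station.  The mass balance
attributes sub-daily O2 change to three processes that act with different
sign and timing: photosynthetic production (GPP, following the light curve),
respiration (ER, constant within a day), and air–water gas exchange (a
linear relaxation toward the saturation concentration, rate KO2).  Daily
parameters are GPP_d and ER_d (g O2 m⁻² d⁻¹; ER is negative by convention
but not constrained) and K600_d (d⁻¹, gas exchange normalised to Schmidt
number 600; constrained ≥ 0).  Within a day, the GPP term uses only the
*shape* of light — PPFD at each step divided by the day's mean PPFD — so
the absolute light calibration cancels; a day with no light has no GPP
term.

Assumptions inherited from the single-station approach: the upstream reach
is well mixed, rates are homogeneous over it, and O2 sources are limited to
photosynthesis, atmospheric exchange and upstream water.  Days violating
these (tidal or intermittent flow, long sensor gaps) are excluded before
fitting; structures such as dams, canals and permitted discharges are
screened afterward against the reach-length distribution rather than used
to drop sites.

### Integration and error structure

The rate equation is integrated with the trapezoid rule.  Gas exchange is
linear in O, so the implicit update solves in closed form per step:

    O[i+1] = ( O[i]·(1 − Δt/2·KO2[i]) + Δt/2·(S[i] + S[i+1]) )
             / (1 + Δt/2·KO2[i+1])

with S the light/respiration/saturation source term.  The state-space
formulation adds iid N(0, σ_proc) process error to each step of the latent
state and iid N(0, σ_obs) observation error to each measurement.  Process
error is per step at the chunk's resolution (not scaled by √Δt), matching
the per-observation formulation; σ_proc is therefore only comparable
between records of equal timestep.  Each day's initial state is pinned to
its first observation — the convention of the model-variant family this
package follows; the source publications do not restate it, so it is
flagged here as a documented choice.  Negative modeled O2 is mathematically
permitted (Gaussian state space) and triggers a warning.

### Marginal likelihood and sampler

Conditional on (GPP_d, ER_d, K600_d, σ_obs, σ_proc) the system is
linear-Gaussian, so the latent O2 states are integrated out *exactly* by a
scalar Kalman filter, vectorised over days and posterior proposals.  The
sampler therefore explores only the daily parameters, node values and
scale parameters — the posterior is identical to sampling states
explicitly, without the dimensionality.  A unit test verifies the Kalman
marginal against closed-form Gaussian marginalisation on a small day.

Sampling uses an affine-invariant ensemble (emcee) with differential-
evolution moves, vectorised likelihood evaluation, and walkers grouped into
`chains` (default 4) pseudo-chains for diagnostics.  Initial walkers are
placed from the preliminary fit (below): GPP/ER at their per-day estimates,
node values from a ln K600 ~ ln Q regression, and daily K600 *on* the
initial node curve so the pooling prior is satisfied from the first step
even when its scale is tight.  Split-Rhat and effective sample size are
computed by arviz (classic split method); zero-variance chains report
Rhat 1.0 with a degenerate-chain warning.  A model whose key scale
parameters (σ_K600_daily, σ_proc) have Rhat > 1.2 is re-run once at 2000
warmup / 2000 saved steps and the re-run is kept regardless.

### Priors and pooling

| parameter | prior | notes |
|---|---|---|
| GPP_d | N(3.1, 6.0) g O2 m⁻² d⁻¹ | literature range |
| ER_d | N(−7.1, 7.1) g O2 m⁻² d⁻¹ | literature range |
| ln K600 node 1 | N(ln 5, 1) | weakly informative; configurable |
| ln K600 node n | N(node n−1, 0.1) | random-walk smoothness |
| K600_d | N(exp(piecewise lnK600(lnQ_d)), σ_K600_daily) | natural scale |
| σ_K600_daily | half-N(0, 0.02 × median preliminary K600) | hierarchical |
| σ_obs | half-N(0, 0.1 mg L⁻¹) | not stated in sources; configurable |
| σ_proc | half-N(0, 0.2 mg L⁻¹ per step) | not stated; configurable |

The K600~Q node grid has spacing exactly 0.2 ln units, anchored at the
minimum observed daily ln Q and extended to cover the maximum (minimum two
nodes).  The daily K600 deviation prior is applied on the *natural* K600
scale, matching the hyperprior's "2% of the median K600" scale; the source
text is ambiguous between ln and natural scale, so this choice is flagged.

The preliminary unpooled fit (independent days, observation error only,
deterministic path) supplies the median K600 that scales the pooling
hyperprior.  It is computed by per-day MAP optimisation over (GPP, ER,
ln K600, ln σ_obs) rather than a full MCMC run: the only quantity consumed
is a median of point estimates, for which MAP is accurate, deterministic
and two orders of magnitude cheaper.  If the preliminary fit is unusable
the scale falls back to a configurable default (K600 = 10 d⁻¹) with a
logged warning.

## Forcing derivation

- **Pressure from elevation**: international standard atmosphere,
  P = 101325·(1 − 2.25577×10⁻⁵·h)^5.25588 Pa.
- **O2 saturation**: Garcia–Gordon (Benson–Krause refit) freshwater
  solubility, converted to mg L⁻¹ with the Kell density polynomial, times
  the moist-air barometric correction (P − p_vap)/(P₀ − p_vap) with
  Magnus-type vapor pressure.  Fit range −1..45 °C; outside it the value is
  extrapolated with a warning.
- **Solar time**: mean solar time shifts 4 min per degree longitude and
  indexes the 04:00–03:59 metabolism day; apparent solar time additionally
  applies Spencer's equation-of-time series (<1 min error) and drives the
  light model.
- **Modeled light**: PPFD = 2326·max(0, sin(solar elevation)) µmol m⁻² s⁻¹,
  with Spencer declination; the 2326 ceiling and the shortwave-to-PPFD
  multiplier (2.114 µmol J⁻¹, ≈45% of shortwave in the PAR band) are
  configurable.
- **Merged light**: coarse observed PPFD divided by modeled PPFD at the
  coarse timestamps gives an attenuation ratio, linearly interpolated
  (endpoint-anchored) onto the fine grid and multiplied back into modeled
  light; night-time ratios are undefined and carried across by the
  interpolation, with output forced to zero wherever modeled light is zero.
- **Hydraulic geometry**: depth = c·Q^f, velocity = k·Q^m with Q in
  m³ s⁻¹ (sensor discharge arrives in ft³ s⁻¹ and is converted by
  0.0283168).  Nonpositive discharge yields a missing value and the day is
  later excluded.

## Input assembly rules

Non-O2 variables are linearly interpolated onto the O2 timestamps.  Gaps
are measured between consecutive available timestamps per variable; a gap
strictly longer than 3 h in any variable excludes every metabolism day
whose 24-h window it overlaps (reason `gap>3h`), while shorter gaps are
filled.  Short O2 gaps are interpolated onto the uniform grid as well, so
every retained day has a complete, uniform-timestep window.  Days whose
windows extend past the record (`incomplete_window`) and days containing
any nonpositive discharge (`nonpositive_flow`) are excluded; each candidate
date carries exactly one primary reason, written to the messages table.
Resolution changes split the O2 record into uniform chunks, one model per
chunk; a new timestep must persist for at least 4 consecutive steps, so
isolated missing or jittered timestamps do not start a chunk.  No despiking
or storm-day filter is applied.

## Assessment

Daily reach length L_d = −ln(1 − 0.8)·v/KO2_d is the 80% gas-renewal
distance (v in m d⁻¹).  Confidence rating uses four metrics computed from
daily posterior *medians*: max Rhat of (σ_K600_daily, σ_proc); the P90−P10
spread of K600_d (gas exchange is constrained by channel form, so spread
> 50 d⁻¹ is physically implausible and < 15 d⁻¹ earns the top band); and
the percentages of GPP_d < −0.5 and ER_d > 0.5 (values within ±0.5 are
treated as indistinguishable from zero).  Any Low-band metric makes the
model Low; all High-band metrics make it High; otherwise Medium; thresholds
are strict inequalities, so a value exactly at a boundary falls to Medium.
Site-level confidence is the minimum over the site's models plus the
comma-joined per-model list.  Structure screening classifies each known
structure distance by the highest reach-length percentile (0, 50, 80, 95)
it strictly exceeds, ties resolving to the lower (more cautious) class;
an unknown structure is reported as beyond the 95th percentile.

## Synthetic sites

The generator emulates the statistical shape of monitoring-network
archives: discharge as a daily lognormal AR(1) (mean ln 5 m³ s⁻¹, sd 0.3,
autocorrelation 0.8) smoothed to hourly and emitted in ft³ s⁻¹; water
temperature as annual + diel sinusoids with sensor noise at the O2
resolution; hourly pressure (standard atmosphere + noise) and hourly
shortwave as clear-sky light times a Beta(4, 1.3) daily cloud factor.
Truth daily parameters follow a K600~lnQ line (10 d⁻¹ at median flow,
slope 0.3 per ln unit, daily sd 0.2), GPP proportional to realised daily
light around a base of 5 (so clouds induce realistic covariation), and ER
around −8 g O2 m⁻² d⁻¹.  The O2 record is produced by the package's own
forward model run sequentially across days with per-step process noise
(0.01 mg L⁻¹) plus observation noise (0.05 mg L⁻¹), with configurable gap
and zero-flow injections.  Defaults describe a temperate mid-order stream
(depth ≈ 0.5 m) in early summer — deliberately inside the identifiable
regime (strong diel amplitude: moderate K600, high GPP).

What the generator does *not* emulate: sensor drift and fouling, storm
hysteresis in the depth/velocity–discharge relations, groundwater O2
fluxes, tidal reversal beyond simple zero-flow injections, or
light-limitation feedbacks.  Passing recovery tests therefore demonstrate
correctness of the inference machinery under the model's own assumptions,
not robustness of the method to real-world assumption violations.

## Problem sizes and numerics

Fits in the tests, analysis scripts and verification script use 4–14 day
records at 15–60 min resolution with 4 chains and scaled-down ensemble
lengths (typically 600 warmup + 300 saved ensemble steps, ~2.3 walkers per
dimension), chosen so a fit completes in seconds to minutes on one CPU
while recovering truth within a few percent; `fit_metabolism` defaults
remain 1000 warmup + 500 saved.  Tolerances: trapezoid vs a 100×-finer
integrator < 0.02 mg L⁻¹; solubility vs an independent oracle < 10⁻⁶
mg L⁻¹; rule engines exact.  Degenerate inputs are handled explicitly:
empty day sets and nonpositive depths raise errors, all-dark days drop the
GPP term, constant chains report Rhat 1.0 with a warning, and an unusable
preliminary fit falls back to a default hyperprior scale.

## Known limitations

- σ_proc is defined per step, so cross-resolution comparisons of process
  error require rescaling.
- Ensemble walkers are not independent chains; grouped-walker Rhat/ESS are
  practical diagnostics, slightly optimistic relative to independent-chain
  MCMC.
- The preliminary fit is a MAP approximation (see above).
- Only the pooled, two-error-source, trapezoid model variant is
  implemented; no observation-error-only or Euler variants, no multi-site
  joint fitting, and no storm-day detection.
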