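# Methods

## Model structure

**Plasma.** Drug disposition in plasma follows a two-compartment model with
zero-order (infusion) input, parameterised by clearance CL (L/h),
inter-compartmental clearance Q (L/h) and central/peripheral volumes Vc, Vp
(L).  The solution is analytic: the central concentration under a running
infusion is a two-exponential expression in the hybrid rate constants, and
finite infusions and multiple doses are assembled by superposition (exact
for linear kinetics).  Plasma parameters are *fixed inputs* — this analysis
estimates nothing on the plasma side; they enter estimation through the
typical profile only, and their inter-individual variability is used only
when simulating virtual populations.  Unbound concentration is
`Cu = FU * C`, with the unbound fraction fixed at 0.70 (linear binding).

**Brain.** Unbound plasma concentration acts as a forcing function for a
linear cascade

    transit' = K_pb * Cu(t - T_lag) - K_pb * transit
    brain'   = K_pb * transit       - K_bp * brain

so brain uptake does not deplete plasma mass.  The lag is an exact time
shift of the forcing, not a stiff approximation.  The transit compartment
relaxes at the same rate constant `K_pb` that governs plasma-to-brain
transfer: only three brain-side rate/lag quantities are identifiable from
interval data of this design, so a separate transit rate is deliberately not
introduced.  Two occasions carry separate parameters: after the first dose
(`K_bp_fd`, `T_lag_fd`) and after multiple doses at steady state
(`K_bp_md`, `T_lag_md` fixed to 0).  When a full course is simulated, the
first-dose parameters govern the first dosing interval and the
multiple-dose parameters apply from the second dose onward, with continuous
state across the switch; whether the transition should instead be gradual is
not identifiable from two-occasion data, and the abrupt switch is the
simplest convention.  At steady state under constant input the
brain:unbound-plasma ratio is `K_pb / K_bp` — the closed form used as a test
oracle.

The reference parameter values used as simulation truth are `K_pb` 0.32/h,
`K_bp_fd` 7.31/h, `K_bp_md` 4.39/h, `T_lag_fd` 2.70 h, IIV on lag 19.7% CV,
combined residual error 0.03 mg/L + 35%.

**Observation.** A microdialysis catheter with dead volume 5.1 µL perfused
at 0.3 µL/min delays fluid by 0.283 h (≈ 0.28 h), subtracted from the *end*
of each 1-h collection interval (the start is left untouched by default; a
flag shifts both ends for sensitivity analysis).  The measured dialysate
concentration is modelled as the time-average of the brain ECF concentration
over the corrected interval, scaled by probe recovery (1.0 by default, the
appropriate value at this very low perfusion flow).  Values strictly below
the LLOQ (0.05 mg/L) are censored; a value exactly at the LLOQ counts as
quantified.

## Numerical scheme

The transit→brain cascade is advanced by a per-step exponential integrator
that is exact when the forcing is linear within a step; the solver grid
refines the requested output grid to 0.01 h (0.02 h in the Monte-Carlo
simulations) and always contains observation-interval boundaries, dose
times and infusion ends.  The integrator also propagates the running
integral of the brain concentration, so interval averages are computed
exactly (under the piecewise-linear-forcing assumption) as differences of
the cumulative integral — no quadrature in the likelihood hot path.  The
generic `interval_average` operation uses adaptive quadrature (absolute
tolerance 1e-10 mg/L·h) with a fixed 129-point Simpson fallback.
Coincident transit/elimination rates are handled by a 1e-8 relative
perturbation guard.  Continuous-infusion simulations run 5 days before the
steady-state evaluation window.

## Estimation

The marginal likelihood integrates, per subject, a single log-normal random
effect on the first-dose lag (`T_lag_i = T_lag_fd * exp(eta)`,
`eta ~ N(0, omega)`).  The default approximation is a **Laplace expansion
with interaction** around the per-subject posterior mode (residual variance
`sigma_add^2 + (sigma_prop * f_ind)^2` uses the individual prediction) —
the same spirit as FOCE-I, chosen for reproducibility without the original
estimation software.  Because the lag can alias between adjacent sampling
intervals, the per-subject objective can be *bimodal* in eta; the inner
step therefore always starts from a global grid scan before refining the
mode (Newton polish, curvature from a 1e-3 central difference).  When all
subjects share one sampling design — always true for the generated studies —
the eta-to-prediction map is tabulated once per outer iteration (cubic
spline through 21 exactly-computed nodes spanning ±6.6 prior SDs) and all
subjects are evaluated in one vectorised pass.  An **adaptive Gauss-Hermite
mode** (32 nodes centred and scaled at the Laplace mode) provides a slower,
more accurate cross-check route.

Laplace accuracy is the usual caveat: on subjects whose posterior is sharp
or kinked — typically BQL-heavy first-dose profiles under M5 substitution —
the Laplace value can deviate from the exact marginal by a few tenths of a
-2LL unit, while the adaptive quadrature stays within ~1e-4 on smooth
cases.  The test suite checks Laplace against direct numerical integration
on a tame toy subject and uses the quadrature mode for tight comparisons.

BQL rows enter either by **M5** — substitution at LLOQ/2 (the convention of
the cited BQL methodology; configurable) and treated as ordinary
observations — or **M3** — contributing `Phi((LLOQ - f)/sd)` to the
likelihood via a numerically stable log-CDF.

Fixed effects, omega and the residual SDs are estimated on the log scale
(positivity by construction); `T_lag_fd` is penalised above the end of the
first-dose observation window (identifiability); `T_lag_md` is always
fixed at 0.  The outer optimiser is Powell's derivative-free method
(xtol 1e-4, ftol 1e-8, up to 8000 evaluations) with optional multi-start
(default 5 jittered starts, fixed seed); if no start improves on the
initial objective the initial values are returned with a failure status, so
the reported optimum is never worse than the start.  IIV is placed on the
lag time only by default (the single identifiable IIV term); additional IIV
terms can be explored by extending the parameter set but are off by
default.

**Diagnostics.** Eta shrinkage is `(1 - SD(EBE)/sqrt(omega)) * 100`;
epsilon shrinkage `(1 - SD(IWRES)) * 100` over quantified rows.  The
condition number is the largest-to-smallest eigenvalue ratio of the
*correlation* matrix of the estimates (with the covariance-matrix version
reported alongside, since conventions differ); the covariance is twice the
inverse of a central-finite-difference Hessian of the objective on the
estimation scale.  The IIV CV% is reported as `sqrt(exp(omega) - 1) * 100`
(exact log-normal CV), the convention also used to convert the reported
19.7% CV into omega = 0.0381.

**Bootstrap** resamples subjects with replacement (default 1000 resamples;
analyses in this repository use smaller counts, stated where run), refits
from the point estimates with a single start, and reports the median and
2.5/97.5 percentiles over converged resamples, warning when more than 20%
fail.  **VPC** simulates replicate studies under the fitted model on the
original design, bins by sampling hour within occasion, and overlays
observed 5/50/95th percentiles on simulated 95% bands; BQL values (observed
and simulated alike) are displayed at LLOQ/2, and censoring is additionally
compared via per-bin BQL fractions.

## Synthetic data

The generator reproduces the design the analysis assumes: per subject it
samples the lag random effect, simulates the brain profile over the full
course, computes interval averages at dead-space-corrected hourly intervals
(7 per occasion), applies recovery, adds combined residual error *on the
interval-average scale* (where the model's residual error lives), and
censors at the LLOQ.  Negative noisy values are retained and flagged BQL —
never truncated — so censored-likelihood handling is exercised.  The
steady-state occasion sits at dose 15 (day 5 of q8h dosing).  Nominal and
corrected interval ends are both stored.

What the generator does *not* emulate: per-patient sampling irregularities,
catheter placement effects, within-subject recovery drift, model
misspecification of the plasma side, or any covariate structure.  Passing
recovery tests therefore demonstrate internal consistency of
estimator and generator under the stated model, not robustness of the model
to real-data violations.

## Monte-Carlo PTA

Virtual subjects draw log-normal IIV on the plasma parameters (per config)
and on the lag time; the brain course is simulated for 5 days and fT>MIC —
the fraction of the final dosing interval (final 24 h for continuous mode)
with brain ECF concentration strictly above the MIC, with linear-
interpolation refinement at threshold crossings and ties counting as not
above — is evaluated on a two-fold MIC grid up to 16 mg/L.  PTA is the
fraction of 5000 subjects with fT>MIC ≥ 50%.  Intermittent fractionations
default to 4 g q8h (12 g/day), 4 g q6h (16 g/day) and 8 g q8h (24 g/day);
extended infusion uses the same fractionation over 3 h (4 h available);
continuous infusion delivers the daily dose at constant rate.  The
pathogen summary maps each MIC50/MIC90 to the nearest simulated MIC at or
below it, flags values below the grid and refuses to extrapolate above it.

**Plasma parameter choice.** This analysis takes plasma parameters as
config input; the shipped default is an illustrative critically-ill
piperacillin set (CL 14 L/h with ~55% CV, Vc 12 L, Q 15 L/h, Vp 10 L, ~30%
CV on volumes), with the wide clearance variability reflecting the broad
renal function typical of such cohorts.  PTA at low MICs (≤ 0.5 mg/L) is
robust to this choice (the packaged sensitivity check swaps in two
alternative sets and warns if PTA shifts by more than 5 percentage points
there), but the *exact* MIC at which a given dose crosses 90% attainment is
driven by the clearance distribution: with the illustrative set, 16 g/day
already attains > 90% at MIC 1 mg/L, whereas a clearance CV above ~65%
would push that boundary to 24 g/day.  Conclusions at the attainment
boundary should therefore be drawn only with a plasma model matched to the
target population.

## Problem sizes used in this repository

Parameter recovery and the acceptance script use 20 replicates × 50
subjects (medians stabilise well before this); the bootstrap driver uses
100 resamples; VPCs use 200 simulated studies; PTA grids use 5000 subjects
(reduced sizes in structural tests).  These are the package's default
working sizes and are stated in each driver's output.

## Known limitations

* Laplace accuracy degrades on sharp/kinked posteriors (see above); the
  quadrature mode exists for verification, at ~30× the cost.
* The plasma model is treated as known; uncertainty in it propagates to
  neither the estimates nor the PTA bands.
* Occasion-specific parameters switch abruptly at the second dose.
* No covariate model, no IIV on rate constants, no plasma-target PTA
  validation (brain ECF is the focus; plasma PTA falls out of the same
  machinery but is not validated here).
* The M5/M3 equivalence holds at low censoring fractions; with heavy
  censoring the methods diverge and M3's likelihood is the principled one,
  at the price of harder numerics.
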