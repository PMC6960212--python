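# Methods

## Process model

The simulator integrates the total-mass balances of an ideally mixed
fed-batch reactor,

    d(xV)/dt = µ·xV
    d(SV)/dt = −(µ/Y_xs)·xV + uf·Sf
    dV/dt    = uf

with biomass concentration x (g/L), substrate S (g/L), volume V (L), feed
rate uf (L/h) and feed substrate concentration Sf (g/L). Growth follows
Monod kinetics, µ = µ_max·S/(K_s + S). The specific substrate uptake rate is
tied to growth through a constant yield, qS = µ/Y_xs, and is reported as a
positive magnitude. Maintenance metabolism, product formation drains on
substrate, gas exchange and broth-density effects are not modeled: the study
is about estimator behavior, not metabolic realism, and any smooth µ(t)
profile exercises the estimators equally.

In the induced configuration an inhibitor is produced in proportion to
biomass from the induction time onward, d(IV)/dt = q_i·xV for
t ≥ t_induction, and attenuates growth non-competitively,
µ = µ_max·S/(K_s+S) · K_i/(K_i+I). This yields a smooth, monotone,
accelerating decline of µ after induction — the canonical shape of an
induced recombinant *E. coli* process — without hand-crafted µ(t)
switching.

The ODEs are solved with LSODA at rtol 1e-8 / atol 1e-10 on a dense 0.01 h
grid, split at the induction time so the production switch-on is a segment
boundary rather than a discontinuity inside a solver step. A mass-balance
audit (|SV − S₀V₀ − ∫uf·Sf dt + ∫qS·xV dt| relative to total substrate fed)
stays below 1e-6 and is enforced by the test suite.

## Packaged study conditions

Two configurations ship as the reference conditions for all evaluation
studies. Their parameters are a reconstruction: chosen once so that the two
processes have the canonical shapes (near-constant µ under exponential
feeding; post-induction decline with substrate accumulation), reach tens of
g/L biomass within a working day-scale cultivation, and sit at the operating
point where the estimator phenomena of interest are expressed — a stepwise
CV floor near 50% at the finest sampling, a worst-case maximum CV near
400%, a smoothing optimum at p ≈ 0.4, and a several-fold spread between the
uptake-rate options. Once frozen, they are treated as fixed study
conditions, not tuning knobs.

| parameter | value | unit | meaning |
|---|---|---|---|
| µ_max | 0.5 | 1/h | maximum specific growth rate |
| K_s | 0.05 | g/L | Monod half-saturation |
| Y_xs | 0.5 | g/g | biomass yield on substrate |
| x0, V0 | 2, 1 | g/L, L | inoculation state |
| Sf | 400 | g/L | feed substrate concentration |
| µ_set | 0.20 (Monod) / 0.19 (induced) | 1/h | design growth rate of the exponential feed |
| t_end | 18 (Monod) / 24 (induced) | h | process duration |
| t_induction | 6 | h | induction time (induced config) |
| K_i | 1 | g/L | inhibition constant |
| q_i | 0.006 | g/g/h | specific inhibitor production after induction |

The feed is exponential, uf(t) = uf0·e^(µ_set·t) with
uf0 = (µ_set/Y_xs)·x0·V0/Sf, which balances delivery against consumption of
a culture growing at µ_set; starting the substrate at the quasi-steady level
S* = K_s·µ_set/(µ_max−µ_set) makes µ constant to well under 1% over the
whole Monod process. In the induced process the feed keeps its uninhibited
schedule, so as growth slows the reactor is progressively overfed and
substrate accumulates (to ≈ 32 g/L by harvest) — deliberately so, since the
interplay of a large feed stream with a declining consumption term is what
separates the uptake-rate formulations.

## Noise model

Measurements are corrupted independently per variable and sampling time:

* biomass, substrate, volume: multiplicative Gaussian,
  σ = (CV/100)·true value, with biomass CV screened over
  {2.5, 5, 7.5, 10, 12.5}% and substrate/volume fixed at 1%;
* feed rate: the *spot reading* gets one additive Gaussian draw per sampling
  interval with σ = 1% of the maximum nominal rate of the process — pump
  precision is specified on full scale, so early in an exponential profile
  the relative error is large;
* the *cumulative* fed substrate is taken from the pump totalizer and
  treated as exact: short-term rate fluctuations average out in the
  delivered volume. (`FeedRecord.from_observed` also offers the fallback of
  trapezoidal integration of the noisy spot rates, for real datasets without
  a totalizer column.)

Observations are clamped at 1e-6 of the initial value so log-based
estimators never see non-positive biomass at these noise levels. All draws
are `numpy` `default_rng` under an explicit seed; replicate i of an ensemble
uses seed + i, so ensembles are bit-reproducible.

What the generator does **not** emulate: autocorrelated analytical drift,
biological batch-to-batch variability (every replicate shares one true
trajectory), sampling-time jitter, missing values, and non-Gaussian error
tails. Consequences for interpretation: passing tests certify estimator
behavior under idealized iid measurement error; on real data, correlated
errors would weaken the spline's advantage less gracefully, and the CV
numbers should be read as lower bounds on real variability.

## Estimators and conventions

**Stepwise log-difference.** µᵢ = ln(Xᵢ₊₁/Xᵢ)/(tᵢ₊₁−tᵢ) on total biomass
X = x·V, stamped at the interval midpoint (phase-neutral against a varying
true rate; `align="end"` stamps at availability time instead). It is exact
for exponential data at any interval — its weakness is pure error
propagation: Var(µᵢ) ≈ 2c²/Δt² for relative biomass error c, which is why
its CV *rises* as sampling gets finer and scales linearly with the
measurement CV.

**Moving average.** Full windows only, so a window-w filter shortens the
series by w−1 points (the endpoint problem). Values are stamped at the
window's mean time by default; `align="trailing"` stamps them when they
become computable, which is the relevant convention for online change
detection and is what the delay study uses.

**Smoothing spline.** The fit minimizes p·Σⱼ(yⱼ−f(tⱼ))² + (1−p)·∫f″(u)²du
over natural cubic splines with knots at the data and unit weights —
the classical SMOOTH/csaps parameterization, with no rescaling of p by knot
spacing or ordinate magnitude (the same p smooths differently scaled data
differently; users of other conventions must convert). Since the objective
equals Σ(y−f)² + λ∫f″² at λ = (1−p)/p, the solve is delegated to
`scipy.interpolate.make_smoothing_spline` for n ≥ 5 points; for n = 3–4 the
Reinsch closed form is used (fitted values a = (pI + (1−p)K)⁻¹py with the
Green–Silverman penalty matrix K, then the natural interpolant through a).
Both paths are verified in the tests against an independent brute-force
minimizer whose penalty matrix is built by numerical quadrature of
natural-basis second derivatives (agreement ≤ 1e-6). p = 0 is handled as
the closed-form least-squares line; p = 1 as natural interpolation. The
growth rate is the logarithmic derivative µ(t) = f′(t)/f(t) of the
total-biomass fit, evaluated at the sample times; the fit must stay
positive there or an error is raised.

**Uptake-rate options.** All three divide by the smoothed total biomass and
report |·|:

1. spline on the total consumption C(t) = SV − S₀V₀ − ∫uf·Sf dt, qS = |C′|/xV;
2. spline on SV, qS = |d(SV)/dt − uf·Sf|/xV — the spot feed term enters
   unsmoothed;
3. spline on S with the dilution rate D = uf/V, qS = |dS/dt − D(Sf−S)|/x.
   Note the division by biomass *concentration*: dividing the volume-reduced
   balance V·dS/dt − uf·Sf + uf·S = qS·xV by V leaves x, and only this form
   recovers the true rate on noise-free data (the x·V form is dimensionally
   inconsistent and fails that check).

One smoothing parameter (default p = 0.4) is shared by the substrate-side
and biomass-side fits of each option.

## Evaluation definitions

* **CV** (Eq. form σ/mean·100) is computed across replicates at each
  timepoint. Grid summaries report the *interior mean* (first and last
  timepoints excluded — every estimator is boundary-biased there and would
  otherwise dominate the average) and the *maximum over all timepoints*.
* The **maximum-CV statistic** on the dynamic process is heavy-tailed at
  n = 100: its denominator, the ensemble mean at the lowest-µ timepoint, is
  itself noisy, so single-ensemble maxima scatter widely. Where a stable
  number is needed (tests, acceptance report) the median of the maxima over
  5 independent ensembles is used.
* **RMSE/MAPE** compare against the true rate linearly interpolated to the
  estimate timestamps; MAPE summaries use interior timepoints, consistent
  with the CV convention.
* The **p screen** evaluates the spline-µ RMSE at *all* sample times,
  endpoints included: endpoint behavior is part of choosing a smoothing
  parameter, and excluding it systematically shifts the optimum toward
  heavier smoothing. The global optimum is the argmin of the
  condition-averaged RMSE; p values whose fit is infeasible (the p = 0 line
  goes non-positive on growing biomass) score NaN and are excluded.
* **Change-detection delay**: the reference time is the first crossing of
  85% of the pre-induction µ plateau by the true rate; the detected time is
  the first downward crossing of the same threshold by the *ensemble-mean*
  estimated curve (per-replicate first crossings are dominated by false
  early triggers for the raw stepwise series at realistic noise). Rates are
  stamped at availability time (stepwise at interval end, moving averages
  trailing), because apparent delay under online monitoring is the quantity
  of interest; with midpoint stamping the filter lag cancels by construction
  and the metric degenerates to sampling noise.

## Problem sizes

Ensembles use n = 100 replicate processes per condition, the package's
standard for stable CV/MAPE summaries. Two statistics sit near shallow
optima and get larger samples: the global p screen runs at n = 300 and the
single coarsest/noisiest condition of the screen at n = 1000 (one condition
is cheap — a few thousand spline fits). The recipe CLI exposes `--reps` for
quick scaled-down runs; n = 20 reproduces every qualitative ranking.

## Known limitations

* The p optimum is broad: between p = 0.3 and 0.5 the condition-averaged
  RMSE varies by ~1%. The value 0.4 is the argmin under the packaged
  conditions, not a universal constant, and must be re-screened for data on
  other time/ordinate scales.
* The spline's natural boundary conditions bias the first and last rate
  estimates (visible as the option-2 underestimate of qS at harvest, where
  d(SV)/dt is accelerating); no boundary correction is attempted.
* The uptake-rate comparison depends on the feed-error model (full-scale
  pump noise, exact totalizer). With strictly proportional spot-rate errors
  the spread between option 1 and options 2–3 shrinks to the smoothing
  effect alone.
* All ensemble replicates share one true trajectory; the CVs measure
  measurement-error propagation only, not process variability.
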