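# Methods

## Flow model and its assumptions

The channel is treated as an infinitely long rectangular duct (width `w`
across `y`, height `h` across `z`) carrying a steady, incompressible,
Newtonian Stokes flow with no-slip walls and a uniform imposed pressure
gradient `G = -dp/dx`. At the study's operating point (1 mL/h through a
~1 mm² section, water-like viscosity) the Reynolds number is of order 0.1,
so inertia, entrance effects and secondary flows are neglected. The
velocity field is the classical double series in
`p_n = (2n+1)π/h`, `q_n = (2n+1)π/w` with the scale
`v₁ = (G/8η)·w²h²/(w²+h²)`; `v₁` is used strictly as the series prefactor,
never as "the centre velocity" (the true centre velocity differs from it
by a few percent, e.g. the square-duct maximum is 0.0737·Gh²/η ≈ 1.18·v₁).

The volumetric rate is linear in `G`, so imposing a syringe-pump flow rate
amounts to one closed-form inversion; `Q` is the canonical drive input
throughout, and `G`, `v₁` are always derived from it. The round trip
`Q → G → Q` is exact to 1e-12 relative by construction.

Biofilm enters the model only through *effective geometry*: a uniform
bottom carpet of thickness `t` leaves an open duct of height `h − t`; two
lateral fronts each advanced by `a` leave a width `w − 2a`. Flow does not
penetrate the biofilm, which simply relocates the no-slip boundary; the
deformability of the interface is ignored. The width reduction is
symmetric (both side walls) — with the five-channel geometry this is the
reading under which the reshaped 250 μm channel reproduces a 72.3 mPa
mid-width maximum at 1 mL/h, which an asymmetric single-front reading does
not.

## Series truncation

The velocity and flow-rate series converge as `1/(2n+1)³` and `1/(2n+1)⁵`;
evaluation and field fitting default to truncation `n = 3`, where fitted
parameters are insensitive to the order (measured: < 0.01% change between
orders 2 and 3, against a stated tolerance of 0.1%).

The bottom shear `σ(y) = η ∂v/∂z|_{z=0}` is evaluated from the analytically
differentiated series, which converges only as `1/(2n+1)²`; shear defaults
to `n = 200` and warns below `n = 100`. At `n = 200` the residual is ~0.1%
of the maximum (visible as a ~0.03 mPa floor at the side walls of the
250 μm channel). Hyperbolic-cosine ratios are evaluated in an
overflow-safe exponential form, so arbitrarily high orders are usable. All
series are evaluated on the distances `|y − w/2|`, `|z − h/2|` (every term
is even), which makes the mirror symmetries bit-exact whenever the
mirrored coordinates themselves are exactly representable.

Verification of the shear map is dual-route: the analytic derivative is
checked against a second-order one-sided finite-difference stencil of the
velocity field at the wall (agreement ≤ 0.2% over 50 interior positions),
against the global force balance `∮σ ds = G·w·h` (≤ 1%), and against the
parallel-plate limit `6ηQ/(wh²)`. On that last point: the exact finite-
width correction is ≈ `0.63·h/w`, i.e. 3.25% at `w/h = 20`, so the 3%
agreement band is checked at `w/h = 25` where the asymptote has been
reached.

## Field fitting

Velocity samples (one per particle streak, `v = (l − d)/t_acq` with the
bead diameter `d` subtracted from the streak length) are fitted to the
analytic field by trust-region nonlinear least squares on normalized
parameters, with multi-start at the nominal geometry ±20% to avoid local
minima and `xtol = 1e-10`. Supported free sets mirror the experimental
designs: `{h}` and `{h, Q}` for biofilm-free and uniformly carpeted
channels, `{w, y₀}` (Q fixed at nominal) for the advancing-front channel
where `y₀` locates the effective no-slip wall, and a sequential procedure
that fits `{h}` per time point at each candidate fixed `Q` and keeps the
`Q` minimizing the total squared residual. In the `(w, y₀)` mode the model
predicts zero velocity outside the effective duct; samples falling outside
it after the first pass are excluded (with a logged count) and the fit is
repeated once.

95% confidence intervals come from the Jacobian-based covariance at the
optimum, `cov = (JᵀJ)⁻¹·SSR/(n−p)`, scaled by the Student-t quantile. The
fit carries no analytic Jacobian; the optimizer's finite-difference one is
adequate because the model is smooth in all parameters. Measured coverage
of the planted height over 100 noisy replicates (5% of maximum velocity,
500 samples) is 95/100.

## Photometric calibration and growth kinetics

Biomass is read from transmitted light as a microscopic absorbance
`A = ln(I₀/I)` (Beer–Lambert analogy; `I₀` is the biofilm-free reference,
~2000 grey levels in the emulated regime). The detector response saturates
at high optical density; measured absorbance is inverted through a
monotone (PCHIP) interpolation of the tabulated true-vs-measured
calibration curve, records at measured absorbance ≥ 0.74 are excluded, and
within the quasi-linear regime (measured ≤ 0.35) the correction moves
values by under 2%. Corrected absorbance converts to cells via
`C_S = c_S·A` (c_S = 3.0×10⁷ cells·mm⁻²) or `N_ch = A/a_N`
(a_N = 1.1×10⁻⁹); the two constants are mutually consistent through the
30 mm² channel bottom area (1/(1.1×10⁻⁹·30) = 3.03×10⁷).

Growth rate `μ` is fitted as `f₀e^{μt}` on corrected absorbance inside the
window [0.02, corrected(0.74)] — the lower edge tied to the lag threshold,
the upper to the retention cutoff — using a log-linear start refined on
the natural scale. The lag time `δ` is the first upward crossing of 0.02,
linearly interpolated between frames (30 frames/h); `μ` is invariant under
a common gain on `I` and `I₀` since the gain cancels inside `ln(I₀/I)`.
Hours are used internally, days only at reporting boundaries.

Front kinematics: `δ = a + b·y` by ordinary least squares over the ROI lag
set (`y` = distance of the ROI's inner boundary from the channel edge);
front velocity `1/b` with standard error `se_b/b²`. Mode classification is
deliberately conservative: *advancing front* requires a positive slope
significant at p < 0.01 **and** a lag range exceeding 3× the median
absolute deviation of the lags; with no significant slope the bundle is
*uniform*; mixed evidence (significant but narrow, or significantly
negative) is *indeterminate*. The range gate alone cannot separate the
modes — for ten i.i.d. Gaussian lags the range is ~3σ while 3×MAD is ~2σ —
so significance carries the decision and the dispersion gate only guards
against trends that are statistically real but physically negligible. Both
thresholds are configurable.

The colonization threshold uses the transparent midpoint rule: the
estimate is the midpoint between the largest colonized and smallest
non-colonized ROI mean shear, the uncertainty half that gap. It is
invariant under record order and duplication. Overlapping classes yield no
point estimate but the overlap interval and a one-sided Mann–Whitney
separation p-value; a logistic-fit estimator was considered and rejected
as the default because with 50 grid points a parametric fit adds
assumptions without narrowing the gap. ROI mean shear is an arithmetic
mean of `σ(y)` on a 1 μm grid. The lag-vs-shear relation in the
sub-threshold regime reports the Pearson correlation with p-value and a
`δ = A·e^{Bσ}` fit; the exponential form is one documented choice among
plausible ones and is swappable.

## Oxygen conversion

Two-point Stern–Volmer calibration: `K_SV = (I_zero/I_ref − 1)/pO₂_ref`
with the air-equilibrated reference at 20% pO₂ by default; a directly
supplied `K_SV` is also accepted. Conversion is the exact algebraic
inverse of the quenching law, so generator round trips are exact at zero
noise.

## What the synthetic generators emulate — and what they do not

All generators draw from `numpy.random.default_rng(seed)` and echo every
planted parameter in a truth block; fixed seeds give byte-identical
outputs.

* **Trails**: bead positions uniform across 2–98% of the width (the
  extreme near-wall strip, where streaks are shorter than a bead diameter,
  is not imaged) and on the 5 μm z-grid; streak length
  `l = v·t_acq + d` + Gaussian length noise; optional out-of-focus
  fraction with corrupted lengths. The planted field uses series order 50.
* **Growth**: per-ROI true corrected absorbance `f₀e^{μ(t−δᵢ)}` after the
  lag, zero before, with `f₀ = 0.02` so the planted lag *is* the 0.02
  crossing (the estimator is then late-biased by under one frame at zero
  noise, by construction). Lags are constant (uniform mode) or
  `δ_edge + yᵢ/v_front` (front mode; 529 μm/day default). Detection
  saturates as `A_meas = s(1 − e^{−a/s})` with `s = 10`, chosen so the
  measured/true deviation stays below 2% at the top of the stated linear
  regime (measured 0.35); intensity noise is Gaussian with σ = 2 grey
  levels — a ROI-averaged grey level pools ~10⁴ pixels, so per-pixel shot
  noise averages to ~0.1% of I₀, consistent with a 0.02 lag threshold
  sitting far above the noise floor. Defaults: μ = 0.5 h⁻¹, edge lag 5 h,
  20 h at 30 frames/h — under which the outermost ROIs of a front-mode
  channel do not reach threshold within the record, exercising the
  not-reached path.
* **Colonization**: ROI mean shear computed by the hydrodynamics module on
  the five-channel grid; colonized iff shear < threshold (11 mPa default).
  Attachment is modelled as sharp; an optional logistic flip scale softens
  it near the threshold.
* **Oxygen**: exact quenching law plus optional Gaussian intensity noise.

These generators share the analysis's own structural assumptions
(exponential growth, sharp fronts, Gaussian noise, a parametric saturation
curve). Passing recovery tests therefore demonstrates the *estimators*
are unbiased and correctly calibrated under those assumptions — not that
real micrographs satisfy them; heavy-tailed intensity noise, streak
segmentation errors, spatially correlated biomass and detachment events
are outside their scope.

## Problem sizes and determinism

Monte-Carlo checks use 100 seeded replicates (500 trails per field fit;
600-frame growth series; the 50-point five-channel colonization grid) —
enough for coverage and bias bounds at the stated tolerances while keeping
the full suite in the tens of seconds. The acceptance script evaluates the
shear maxima at truncation 200 and the truncation-sensitivity fit on a
seeded, jittered 20×20 noiseless grid. Degenerate inputs fail loudly:
single-class colonization records, single-z sampling with free height,
non-monotone calibration tables, occluding effective geometries and
decimal-comma CSVs all raise typed errors rather than returning numbers.
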