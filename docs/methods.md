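# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the limitations of the `pbmwound` analysis pipeline.

## Study design emulated

A 4-arm excision-wound phototherapy study in genetically diabetic (db/db)
mice: a ø 1.4 cm full-thickness dorsal wound (initial area π·7² ≈ 153.9 mm²)
per animal, 8 animals per arm (sham control and red/green/blue pulsed LED
therapy), wound planimetry (area, perimeter, depth) every 4th day through
day 28, 6-minute therapy sessions with wound-surface thermography at 20 s
intervals plus pre/post core temperatures, and stereoscopic wound
photographs flanked by an 18%/90% reference card taken under the therapy
illumination.

## Wound-closure kinetics

Relative area is `100·A(t)/A(0)` per animal (observed day-0 denominator).
The closure model is the exponential plateau

    %W(t) = (W0 − Wp)·exp(−k·t) + Wp,

fitted by unweighted nonlinear least squares to the individual measurements
pooled within an arm (per-animal fits are available as an option). `W0` is
left free rather than pinned at 100%: the day-0 measurement is as noisy as
any other and the early gaping transient (below) lifts the apparent
intercept. Initialization: `W0` ← mean at the earliest day, `Wp` ← mean at
the latest day (or the extreme value for rising curves), `k` ← the
log-linear slope of the plateau-shifted values, with bounds
`k ∈ [1e−8, 10]` per day. A fit whose rate constant collapses onto its
lower bound (flat data) is refit as a constant mean and flagged
`degenerate`; its band is the standard error of the mean. The parameter
covariance is the Jacobian-based Gauss–Newton estimate scaled by
`RSS/(n−3)`.

Milestones invert the fit in closed form,
`t(level) = −ln((level−Wp)/(W0−Wp))/k`; levels at or below the plateau are
reported as unreachable rather than clipped.

**Delay curve.** For a treated and a reference (control) arm, the admissible
levels are those reached by *both* fitted curves within the horizon
`t_max = 28` d (the observation period); `delay(level) = t_ref − t_trt`.
The maximizer is located on a 2000-point level grid and refined by bounded
scalar optimization; when the delay is monotone over the admissible range —
the generic situation when both curves are still descending at the horizon —
the boundary value is reported and flagged `boundary=True`. A finite
interior maximum only exists under the horizon restriction. Because the two
curves reach the maximizing level on different days, both clocks
(`day_ref`, `day_trt`) are reported rather than a single unlabeled day.
Negative delays (treatment slower) are reported as-is.

**Healing rate.** `(A1−A2)/(0.5·(P1+P2))/(T2−T1)` in mm/day, evaluated at
each interior sampling day with the nearest flanking visits as endpoints
(with 4-day sampling this spans an 8-day window). The statistic is exactly
antisymmetric under swapping the endpoints; gaping gives negative rates.

## Wound shape

Circularity is `2√(πA)/P`, the ratio of the area-based to the
circumference-based circle-equivalent radius (equivalently the square root
of the isoperimetric quotient `4πA/P²`): 1 for a circle, → 0 for a linear
cut, scale invariant, and ≤ 1 for any simple closed outline.

Mask-based measurement takes the area as the pixel count times the pixel
area, and the perimeter as the marching-squares 0.5-level iso-contour length
of the mask after a σ = 1 px Gaussian smoothing. The smoothing places the
contour at the sub-pixel boundary; the raw binary contour staircases and
overestimates a disk's perimeter by ~6% (boundary-pixel counting by up to
~27%), both of which would push rasterized disks visibly below circularity 1
and break the isoperimetric bound. Structures so thin that they vanish
under smoothing (1-px lines) fall back to the raw binary contour, which is
accurate for them. Masks must contain a single connected component.

The eccentricity-vs-size regression reuses the plateau-exponential form with
wound size (mm²) as the independent variable and the plateau at large sizes,
so elongated shapes concentrate at small sizes. The 95% mean prediction
band is the delta method (`√(gᵀCg)` scaled by the Student-t quantile at
n−3 df). Whether "size" is absolute mm² or % of initial is up to the
caller; the module only requires a consistent column.

## Thermal response and dosimetry

Per treated reading, `ΔT(t) = (T(t)−T(0)) − mean_ctrl(T(t)−T(0))`: the sham
arm defines zero external heating, and `ΔT(0) = 0` exactly. The correction
uses the control-arm mean (a pooled zero reference), not matched pairs. The
irradiative component is fitted through the origin with
`ΔT(t) = Ts·[1−exp(−k·t)]`; the CI on `Ts` is a Wald t-interval at n−2 df
(profile-likelihood intervals are deliberately not implemented). Negative
fitted `Ts` is permitted and flagged.

Onset detection reports the duration of the control arm's flat phase: the
grid time immediately preceding the first deviation of the control mean
from its t=0 value by more than the tolerance (default 0.05 °C); a control
that never deviates returns infinity, and tolerance 0 on noisy data
degenerates to t=0.

Radiant exposure is `irradiance/1000 · duration` J/cm², optionally scaled
by a pulsing duty factor. The default applies **no** duty factor: the
study's dosimetry quotes the time-averaged target irradiance (40 mW/cm²
over 360 s → 14.4 J/cm²), and only that accounting is self-consistent with
the quoted dose, so the 50% duty cycle of the pulsed source is an explicit
opt-in argument.

## Reflectance calibration

Pipeline per stereoscopic view: piecewise sRGB EOTF decode of the 8-bit
image → linear-sRGB-to-linear-Adobe-RGB(1998) primaries conversion (single
matrix through CIE XYZ; both spaces are D65, so no chromatic adaptation) →
select the channel matching the therapy wavelength (off-channel signal is
sensor crosstalk, not tissue signal) → average over the wound and card-patch
masks → affine two-point calibration sending the measured patch means
exactly to 0.18 and 0.90. Views are calibrated independently (each sees its
own card) and averaged afterwards. Because the pipeline re-linearizes after
the conversion, the Adobe encoding gamma (2.19921875) cancels and only the
primaries change; the conversion is retained for fidelity to the imaging
protocol and can be bypassed for pure-sRGB work by using the decoded values
directly. Regions with more than 1% of pixels at encoded values ≥ 254
raise a saturation error. The two-point calibration absorbs sensor gain
and offset, so the reported fraction is gain invariant up to quantization.

## Synthetic cohort generator

The generator produces data with the statistical structure the analyses
assume; its defaults are the study conditions.

* **Trajectories.** Mean relative area = plateau model + a Gaussian-in-time
  gaping bump (amplitude 25%, centre day 4, σ 1.5 d), anchored to zero at
  day 0 so the pre-noise day-0 value is exactly `W0`. The bump reproduces
  the early gaping (areas above baseline at day 4) while the fitting stage
  deliberately ignores it, mirroring the study's use of a pure plateau fit
  on gaping data. Arm kinetics defaults (`W0`, `Wp`, `k` = 100/25/0.065
  control, 100/20/0.080 red, 100/22/0.074 green, 100/25/0.067 blue) were
  chosen so the fitted milestones land near the reported ones (red t50
  ≈ 12.3 d, control ≈ 16.9 d, red day-12 area ≈ 51%). Measurement noise is
  multiplicative lognormal with unit mean and CV 0.15 (areas are positive
  with roughly scale-free dispersion; the magnitude is not reported in any
  source and was set to visually plausible dispersion — it is
  config-exposed, not a claimed study value).
* **Perimeters** derive from the area and a wound-size-dependent
  eccentricity, itself plateau-exponential in size: 0.95 at large sizes
  declining toward 0.735 as the wound closes, inverted via `P = 2√(πA)/ecc`.
* **Temperature sessions.** Baseline 33.5 °C; a delayed-onset internal
  drift shared by all arms (flat for 140 s, then 0.004 °C/s); treated arms
  add `Ts·(1−exp(−k·t))` with `Ts` = 0.80/1.54/1.73 °C (red/green/blue, the
  midpoints of the reported CI ranges) and `k` = 0.012 /s; additive
  Gaussian noise (SD 0.1 °C). Paired core temperatures shift by
  0.50/0.30/0.15/0.10 °C (red/green/blue/control).
* **Scenes** are rendered in linear sRGB — channel intensity ∝ reflectance ×
  gain, off-channels at 4% crosstalk, Gaussian sensor noise SD 0.005 — then
  sRGB-encoded and quantized, i.e. the exact inverse of the measurement
  pipeline's linearization step. (Constructing pure-channel colours in
  Adobe space and inverting the primaries matrix would leave the sRGB gamut
  and clip; since the conversion is linear, proportionality — and hence the
  calibration round-trip — is unaffected.)
* **Reproducibility.** One master seed; each animal draws from a substream
  keyed by a stable hash of (seed, group label, animal index), so extending
  the design never perturbs existing animals, and identical config + seed
  gives byte-identical tables.
* LDI perfusion and pre/post erythema scores are plain group-shifted
  Gaussians — enough to exercise the statistics stage, with no pretence of
  speckle or colour physics.

What passing tests on these data do **not** show: robustness to real-world
artefacts (missing visits, segmentation error, heteroscedastic planimetry,
non-lognormal outliers, illumination gradients across the reference card),
since the generator contains none of them.

## Statistics

Shapiro–Wilk per group at α = 0.05 gates (but does not abort) the ANOVA
flow. The group comparison is a two-way (arm × day) OLS ANOVA; the
treatment-vs-control contrasts use the marginal arm means with the ANOVA
residual variance, adjusted by the classical single-step Dunnett
multivariate-t procedure. The joint tail probability
`P(max_i |T_i| ≥ t)` is evaluated by deterministic quadrature over the
one-factor representation (64-node Gauss–Hermite for the shared control
factor × 128 equal-probability chi nodes for the pooled scale), accurate to
~1e-4 and reproducible without Monte Carlo; adjusted p-values are clamped
to be ≥ the raw t-test p. Repeated measures per animal across days are
treated as independent observations, as a plain two-way ANOVA does — a
caveat, not a recommendation. The paired Wilcoxon signed-rank test uses the
exact null distribution for n ≤ 25 without zeros, so eight one-signed pairs
give exactly p = 2/256 = 0.0078125 two-sided.

## Numerical choices and degenerate inputs

* Fits: `scipy.optimize.curve_fit` (trust-region reflective under bounds)
  with analytic Jacobians; non-convergence raises with the optimizer's
  message rather than returning garbage.
* `time_to_level` forward-evaluates to 1e-9; inversion loses relative
  precision only within ~1e-6·(W0−Wp) of the plateau.
* Day-0 areas of zero, empty masks, fragmented masks, empty control groups,
  inverted calibration patches, out-of-range encodings and all-zero paired
  differences raise typed errors naming the offending field or line.
* All CSV output is plain UTF-8 with "." decimals; units are fixed (mm²,
  mm, day, s, °C, mW/cm²) and converted only at the I/O boundary.

## Known limitations

* With the study's slow closure kinetics (`k·t_max ≈ 2`), the plateau is
  only partially observed within 28 days, so `(k, Wp)` trade off along a
  flat likelihood valley: at n = 8 per arm and 15% measurement CV the
  pooled-fit medians of `|Δk|/k` and `|ΔWp|/Wp` are ≈ 0.17 and ≈ 0.20
  (measured over 200 replicate cohorts). The reported milestone t50 is
  nonetheless essentially unbiased (< 1 day). Conclusions should rest on
  milestones and delay curves, not on `k` or `Wp` individually.
* The pooled arm fit ignores animal-level correlation; no mixed-effects
  extension is provided.
* No wound segmentation, 3D depth reconstruction, erythema scoring or LDI
  physics: masks, depths and perfusion/erythema values are inputs.
* Problem sizes in the verification suite (e.g. 200 recovery cohorts, 500
  CI-coverage replicates, 1000 null-calibration replicates) are the
  package's chosen defaults for stable Monte-Carlo estimates at desk scale.
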