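# Methods

This note documents the models implemented in `dendro_isophys`, the choices
made where the underlying methods literature leaves options open, what the
synthetic-data generator does and does not emulate, and the package's known
limitations.  No empirical claim is made here beyond what the test suite
and `scripts/acceptance.py` themselves compute.

## Carbon-isotope physiology

Discrimination uses Δ¹³C = (δ¹³C_atm − δ¹³C_p)/(1 + δ¹³C_p/1000) with
δ¹³C_p = δ¹³C_sample − d_offset.  The post-photosynthetic offset
d_offset = 2‰ is applied to both bulk wood and α-cellulose by default; the
wood–cellulose difference is instead carried as an explicit indicator term
in the attribution models, mirroring how mixed wood/cellulose datasets are
usually analysed.  Material-specific offsets are configurable.

Intercellular CO₂ comes from either the simple model
ci = ca(Δ¹³C − a)/(b − a) or the photorespiration-corrected form
ci = [(Δ¹³C − a)ca + f·Γ*]/(b − a); the corrected form is the pipeline
default.  Constants: a = 4.4‰, b = 28‰, f = 12‰, Γ*₂₅ = 42.75 ppm.  The
Γ* temperature response is a single Arrhenius exponential
(Ea = 37.83 kJ mol⁻¹) anchored at 25 °C; the elevation correction treats
the compensation point as a fixed partial pressure, so the mole fraction
scales with P₀/P(z) under the 1976 standard atmosphere (at the default
1030 m this is a factor 1.127).  Leaf temperature is the April–August mean
of the year (or the mean over a pooled segment's years).

Pooled 5-year wood segments use the arithmetic mean of the annual drivers
(ca, δ¹³C_atm, T_Apr-Aug) over the segment's calendar years.  The whole
chain is algebraically inverted for the generator; the only approximation
arises when annual δ¹³C is pooled and then inverted with segment-mean
drivers, a relative error below 0.5 % for smooth trajectories (asserted in
the tests).

## Oxygen-isotope chain

Δ¹⁸O_lw = (Δ¹⁸O_tr − ε_wc)/(1 − p_x·p_ex) with p_x = 1 by default.
p_ex = 0.36·VPD + 0.13 is computed once from the site-mean VPD (default
0.6 kPa, a plausible montane growing-season mean; the value is a config
knob because site VPD is rarely published) — a per-year mode exists behind
a flag.  ε_wc defaults to the constant 27‰; a temperature-dependent mode
uses the published quadratic 0.0084·T² − 0.51·T + 33.63 (≈26.8‰ at 20 °C,
decreasing over 5–30 °C).  The precipitation-δ¹⁸O hindcast is an OLS
regression of the instrumented series (default calibration window
1950–2020) on annual mean temperature and annual SPI; observed years keep
their observations and each year carries an observed/hindcast provenance
flag.  Coefficients are always re-fit from the supplied data.

## Growth and releases

BAI is computed from the cumulative radius (pith offset default 0, i.e.
radii are measured from the innermost ring; cambial age likewise counts
from the innermost measured ring).  Percent growth change uses 10 + 10 year
windows, PGC = 100(M2 − M1)/M1.  The boundary line bins prior growth into
10 equal-count bins, takes the mean of the top decile of PGC per bin, and
fits a·exp(−b·x) + c through the bin points; evaluation outside the fitted
range clamps to the nearest bin (logged).  A release year is PGC strictly
greater than 50 % of the boundary value; consecutive release years merge
into one event with its peak recorded.  The boundary line is meaningful
only when estimated from a pooled multi-tree dataset whose upper envelope
reflects real release responses.

## Segmented regression

Breakpoints are estimated by iterating OLS on {x, (x−ψ)₊, −1(x>ψ)} and
updating ψ ← ψ + γ̂/β̂ until max|Δψ| < 1e-4 (max 100 iterations; ψ₀ at the
k/(k+1) quantiles, 5 seeded random restarts).  At moderate signal-to-noise
the iteration can cycle between nearby candidates; in that case the
estimate falls back to the exact profile-RSS minimizer over the observed x
grid (coarse-to-fine pair scan for k = 2), which is the estimator's
defining objective, with ties broken toward the earlier year.  SE(ψ̂) is
the delta-method ratio SE(γ̂)/|β̂|; per-segment slopes and SEs come from
the OLS refit at frozen ψ̂.

The number of breaks (0–2) is chosen by forward sequential testing using a
Davies-type supremum test: the largest |t| of an added hinge term over 30
candidate positions restricted to the interior 5–95 % quantile range (edge
segments of a handful of points otherwise dominate the supremum by chance),
with the p-value from the Davies bound
p ≤ 2Φ(−M) + V·e^(−M²/2)/√(8π), V the total variation of the statistic
along the grid.  The bound is conservative, which keeps the empirical
type-I rate at or below the nominal 0.05 (checked at 500 replicates).
Chronology fits default to the 1818–2020 window and a minimum of 5 points
per segment.

A calibration caveat, verified by simulation and relevant to interpreting
breakpoint SEs: the delta-method SE is approximately nominal only when the
underlying trend is genuinely piecewise linear and the slope change is
well identified.  For chronologies whose expectation is a smooth multi-knee
curve, the fitted ψ̂ moves with noise far more than SE(ψ̂) suggests.

## Mixed-effects attribution

The observation unit is the native sampling step: annual rows for cellulose
series and ring widths, one row per pooled 5-year segment for bulk wood —
BAI_ln is accordingly modelled as the segment mean of annual ln BAI on the
wood trees, so the three responses share their observation grid.  The
model is a per-tree random intercept with AR(1) errors whose lag is counted
in native steps; it is fitted by full ML with the likelihood profiled over
β and σ², leaving a 2-parameter (ρ, σ_b²/σ²) Nelder-Mead problem; the AR(1)
whitening and a Sherman-Morrison rank-one update make each likelihood
evaluation O(n·p).  σ denotes the stationary residual SD.  A fit against
R's nlme (ML, corAR1) on a small dataset agrees to ≲1e-3 in all parameters
and is part of the test suite.

AICc uses k = (number of fixed effects incl. intercept) + 3 covariance
parameters; this convention is stated so ΔAICc tables are reproducible.
All marginality-respecting subsets of the main effects and CO₂ interactions
are fitted (guard at 4096 models), the ΔAICc < 2 set is averaged
conditionally (each term over the models containing it, Akaike weights
renormalized), and unconditional SEs add the between-model variance.
p-values are two-tailed normal (Wald z).  Marginal/conditional R² are the
fixed / fixed+random variance fractions with var(Xβ̂) as the fixed part.
VIF is computed per continuous predictor with an intercept in the auxiliary
regressions; exact collinearity reports infinity.  PCA is an
eigendecomposition of the correlation matrix with components signed so the
largest-|loading| variable is positive.

## Synthetic data: what it emulates, and what it does not

The generator builds a three-species, 35-tree study: 12 beech and 12 fir
with 5-year pooled bulk-wood δ¹³C/δ¹⁵N, 11 spruce of which 5 carry annual
α-cellulose δ¹³C/δ¹⁸O, recruitment 1430–1700, analysis window 1501–2020.
Drivers are piecewise linear with noise: CO₂ 280→414 ppm accelerating after
1966 with a Suess-effect δ¹³C_atm decline, an N-deposition hump peaking in
1989 collinear with a precipitation-pH trough in 1988 (pre-industrial pH
5.8), warming of 0.44 °C/decade after 1974, and AR(1) SPI indices.

Responses are linear in the Z-scored drivers with per-tree random
intercepts and AR(1) process noise, then pushed through the exact inverse
of the physiology chain; wood values are pooled tree-anchored (counted back
from the most recent year, incomplete oldest remainder dropped) and
measurement noise (0.06/0.07‰ δ¹³C, 0.17‰ δ¹⁸O, 0.11‰ δ¹⁵N — typical
replicate precisions) is added after pooling.  Coefficient magnitudes were
chosen so the marginal/conditional R² of the fitted models land in the
ranges typical of published multi-century attribution studies (iWUE ≈
0.7–0.8 / 0.8–0.9; δ¹⁵N ≈ 0.15–0.45 / 0.5–0.6; BAI_ln ≈ 0.55–0.7 /
0.55–0.75).  The leaf-water chronology is prescribed as an explicit broken
line (break 1877, +0.007 then −0.003 ‰ yr⁻¹) with noise components sized so
the chronology residual SD is ≈0.12‰, the level at which the delta-method
2·SE interval for ψ̂ attains near-nominal coverage; this forces the
synthetic δ¹⁸O_p hindcast residual to be small (calibration R ≈ 0.99),
higher than instrumented precipitation networks typically achieve.
The Monte-Carlo recovery studies search a reduced candidate model space
(cambial age, CO₂, N deposition, pH plus the key CO₂ interactions, ~20–40
models per response) so a 50-replicate end-to-end study runs at desk scale;
single runs default to the full 6-main/5-interaction space.

Not emulated: species interactions, mechanistic photosynthesis or N-cycle
dynamics, missing rings and cross-dating error, cellulose-extraction
artefacts, random slopes, or non-stationary driver–response relationships.
Passing recovery tests therefore demonstrates correctness of the estimation
chain under the stated statistical model, not robustness to those realities.

## Numerical choices and degenerate inputs

Z-scoring uses the sample SD (ddof = 1) and errors on zero variance.  The
LME optimizer re-starts from fixed alternative points if Nelder-Mead does
not converge; ρ is bounded to (−0.99, 0.99) by a tanh transform and
λ = σ_b²/σ² is optimized on the log scale.  λ = 0 with ρ = 0 reduces
exactly to OLS (tested to 1e-6).  Inversion of iWUE targets requires
0 < iWUE < ca/1.6, with the boundary rejected.  BAI = 0 rows are excluded
from ln BAI with a logged count.  RWL files honour the 999 (0.01 mm) and
−9999 (0.001 mm) stop-marker conventions; widths are written rounded to the
unit resolution, so file round trips are exact only to 0.005 mm.

## Known limitations

- Breakpoint SEs are delta-method approximations; see the calibration
  caveat above.  Bootstrap or profile-likelihood intervals are not
  implemented.
- Group-level contrasts (e.g. a material offset identified from ~11 trees)
  have t-like sampling distributions with few effective degrees of freedom;
  2·SE normal intervals under-cover them by construction under ML.
- REML refits for visualization, random slopes, and non-Gaussian responses
  are out of scope.
- The boundary-line instantiation (equal-count bins, top decile,
  negative-exponential smoothing) is one concrete, testable variant of the
  release-detection approach; other published variants differ in detail.
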