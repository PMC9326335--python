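# Methods

This note records the models, the defaults and the reasoning behind the
design choices, in the spirit of the model documentation shipped by
statsmodels or msprime.  It states no empirical number that the test suite
or `scripts/acceptance.py` does not itself compute.

## Spectral forward model and inversion

Tissue reflectance over the 450–650 nm fit range (Soret shoulder plus both
oxyhemoglobin Q-bands) is modelled by a closed-form surrogate

    R(μa, μs′) = μs′ / (μs′ + k₁ μa) · exp(−k₂ √(μa μs′) d),

an albedo-like term carrying the absorption contrast times a weak
pathlength correction.  The constants (k₁ = 8, k₂ = 0.4, d = 0.01 cm) were
fixed once so that R is strictly decreasing in μa and strictly increasing
in μs′ over the lookup-table domain μa ∈ [0.01, 50], μs′ ∈ [1, 50] cm⁻¹;
the `LUT` constructor enforces both monotonicity invariants on its nodes
and interpolates bilinearly in (log₁₀ μa, μs′).  The surrogate is
pluggable: any callable R(μa, μs′) — including a measured phantom table —
can replace it in `forward_reflectance`, `build_lut` and
`invert_spectrum`.  No photon-transport or probe-geometry realism is
claimed; what the surrogate guarantees is a well-posed, monotone forward
problem on which round-trip parameter recovery is testable.

Absorption combines the two hemoglobin species,
μa(λ) = ln10 · (tHb / 64 500 g mol⁻¹) · [StO₂ ε_HbO₂ + (1−StO₂) ε_Hb],
with reduced scattering μs′(λ) = a (λ/630 nm)^(−b).  The extinction table
is a *synthetic* analytic approximation (Soret-tail exponentials plus
Gaussian Q-bands at 542/577 nm for HbO₂ and a broad 555 nm band for Hb),
not a published compilation; it is qualitatively correct (positivity,
double-dip signature, Q-band crossings, Hb > HbO₂ in the red) and the
same table is used forward and inverse, so perfusion estimates are
self-consistent.  A measured table can be loaded from CSV.

Inversion is bounded least squares (scipy `least_squares`, trust-region
reflective) over θ = (tHb ∈ [0.1, 100] g/L, StO₂ ∈ [0, 1],
a ∈ [1, 60] cm⁻¹, b ∈ [0, 3]) restarted from a fixed 4-point grid; the
best of the converged starts wins.  Artifact screening rejects spectra
with any raw count at the 16-bit ceiling ("saturation"), median calibrated
reflectance below 0.005 ("low signal"), or post-fit RMSE above 0.02
("high residual") — thresholds are configuration defaults, since the
original instrument's criteria are not public.  Replicate spectra of a
tumor-visit are averaged after screening, before inversion.  StO₂ recovery
is accurate to ±0.01 and tHb to 2% relative on noise-free data (enforced
over a 4×4×3×3 θ grid); tHb is the least identifiable parameter under
noise because it trades off against scattering amplitude.

Fold changes are per-tumor: value(week)/value(week 1), tumors lacking a
positive week-1 baseline being excluded and logged.  Group-baseline
normalization was the alternative; per-tumor was chosen because it removes
multiplicative between-tumor offsets and is the natural reading of
per-tumor longitudinal fold-change plots.

## Pfaffl quantification

Triplicates whose Ct range exceeds 0.5 cycles drop the single well
farthest from the median (flagged); the 0.5-cycle rule is a lab convention,
configurable.  260/280 bounds (1.8–2.0) are inclusive.  Efficiencies come
from standard-curve slopes, E = 10^(−1/slope), with non-negative slopes
rejected.  The calibrator Ct per gene is the arithmetic mean over
control-group week-1 samples (mean vs median was open; mean is the common
choice and is configurable), applied per sample — so the *geometric* mean
of the calibrator group-week ratios is exactly 1.  When every E = 2 the
ratio collapses to 2^(−ΔΔCt), which the tests exploit as an oracle.

## Group-smooth GAM

The response (fold change or relative expression) is modelled as
y = α_g + f_g(week) + ε, ε ~ N(0, σ²) i.i.d., one smooth per arm — the
factor-smooth interaction form.  Each f_g is a P-spline: k = 6 uniform
(unclamped) cubic B-splines on [1, 6] with a second-order difference
penalty on the coefficients.  Uniform knots matter: they make
coefficients-linear-in-index coincide exactly with functions linear in
week, so straight lines are never shrunk and the λ→∞ limit is the
per-group OLS line (a tested closed-form oracle).  The sum-to-zero
constraint over each group's observed weeks is absorbed through the null
space of the column-sum functional, leaving identifiable group intercepts.
k = 6 matches the six weekly visits (one basis function per visit, the
maximum the design identifies plus curvature headroom); it is
configurable up to (distinct weeks + 2).

Smoothing parameters (one λ per arm) minimize the REML criterion
(n−M)·log(D_p/(n−M)) + log|XᵀX + Σλ_gS_g| − Σ_g rank(S_g)·log λ_g by
coordinate descent over 40 log-spaced grid points in [10⁻⁴, 10⁶] with
golden-section refinement.  GCV (n·RSS/(n−tr A)²) is available via
`fit(method="gcv")`; REML is the default because our own coverage
simulations showed GCV's occasional undersmoothing-in-sympathy-with-noise
degrades the calibration of intervals computed conditional on the selected
penalty, while REML-selected fits are calibrated — the same behavior
documented in the smoothing literature.  Fixed penalties can be forced
with `fit(lam=...)`.

Coefficient uncertainty is the Bayesian posterior covariance
V = σ²(XᵀX + Σλ_gS_g)⁻¹ with σ² = RSS/(n − tr A).  REML-selected fits also
carry a smoothing-uncertainty-corrected covariance V + J V_ρ Jᵀ, with
J = ∂β̂/∂ρ (ρ = log λ, central differences, step 0.3) and V_ρ twice the
inverse of the numerical REML Hessian, its curvature floored at 0.05 so
boundary-flat penalties cannot inject unbounded variance.  The package's
own `coverage_simulation` studies fixed the defaults: pointwise curve
intervals use the corrected covariance, simultaneous difference bands the
conditional one (whose max-statistic calibration is already nominal, the
corrected version being conservative for whole-function coverage).

## Simultaneous difference bands

The pairwise comparison d(x) = f_A(x) − f_B(x) includes the group
intercepts by default (whole-trend comparison; a smooth-only flag exists).
The 95% simultaneous band is d̂ ± m*·SE with m* the empirical 0.95
quantile of max over the 200-point grid of |L(β*−β̂)|/SE across 10 000
draws β* ~ N(β̂, V); m* ≥ 1.96 by construction.  Grid points with
SE < 10⁻¹² are masked to avoid 0/0 at constrained points.  Significant
windows are contiguous runs where the band excludes zero, with endpoints
refined by linear interpolation of the band-edge zero crossing and
one-cell excursions flagged short.  The three pairwise comparisons per
metric are reported without further multiplicity correction: each band is
already simultaneous across time, which is the protection the analysis
relies on.

## Synthetic cohort

Arm sizes default to the study's (MTD 27, MET 20, CG 14).  Group trend
templates are monotone piecewise-cubic (PCHIP) interpolants through
(week, level) anchors on the fold-change scale: CG flat; MET StO₂ rising
to 1.08 at week 4; MTD to 1.05 at week 3; tHb rising to 1.13 (MET) / 1.11
(MTD) by week 6 — so the derived HbO₂ fold peaks near 1.15/1.10, matching
the reported maxima without a separate template; MTD *Vegf* and *Hif-1a*
start at 0.5 and recover.  Per-tumor heterogeneity is an additive Gaussian
offset on the fold scale (SD 0.02), constant over weeks.  Baselines
(StO₂ 0.60, tHb 15 g/L, a 20 cm⁻¹, b 1.2) are typical soft-tissue values.
Spectra get 1% multiplicative noise; visits go missing completely at
random (rate 0.05 — the study reports missingness but no mechanism);
spectra are corrupted at rate 0.05 with one of three archetypes
(saturation, near-dark, baseline shift) mirroring the reported causes
(movement, breathing, pressure); three replicate spectra per visit
(the original per-visit count is unstated; configurable).  Ct tables are
triplicate with 0.15-cycle well noise, per-gene efficiencies in
[1.88, 2.0], and standard curves with slope −1/log₁₀E.  Masks are
3-class label images whose positive-pixel fraction is drawn around group
means 25/24/8% (CG/MET/MTD).  Scores drift upward for CG/MET and downward
for MTD across the nine categories.

What the generator does *not* emulate: mechanistic tumor growth or
pharmacokinetics, image texture, informative missingness, within-tumor
serial correlation beyond the constant offset, or instrument-specific
spectral artifacts.  Passing tests therefore demonstrate correctness of
the algorithms under the stated noise model, not robustness to every
failure mode of real endoscopic data.

## Calibration scenarios and problem sizes

The coverage studies behind the acceptance script use i.i.d. Gaussian
residual noise, matching the model's exchangeability assumption (the
model deliberately has no random effects).  The noise SD (0.02) is the
StO₂ fold-change residual scatter that the default generator actually
produces once spectra are calibrated, inverted and normalized — measured
from the pipeline, not assumed.  The canonical truth is a gentle trend
(1 → 1.04 at week 3 → 1.01); the null scenario gives it to both arms.
Problem sizes: 500 replicates for the two coverage rates, 200 for effect
detection, n = 20 tumors/arm, 6 visits, 200-point grids, 10 000 posterior
draws — sizes at which the binomial error of a coverage estimate is about
one percentage point.

Known limitation: for truths with sharp local curvature relative to the
interval width (e.g. a pronounced peak at low noise), penalized-spline
intervals lose a few points of across-the-function coverage to smoothing
bias; this is inherent to conditional-on-smoothness inference and affects
reference implementations at least as strongly.  Detection of such peaked
effects (the week-4 window study) is unaffected.

## Numerical details and degenerate inputs

Penalized systems are solved by Cholesky factorization; the posterior
root falls back to a clipped eigendecomposition if Cholesky fails.
Duplicate (tumor, week) scores, non-amplifying standard curves, missing
calibrator samples, masks without tissue, groups with fewer than two
distinct weeks, extrapolation beyond the basis domain and non-positive
calibration denominators all raise errors naming the offending item.
All-tied Kruskal–Wallis input short-circuits to H = 0, p = 1.  Every
random routine takes an explicit seed; the pipeline derives per-stage
seeds from the global one by hashing the stage name, so toggling stages
does not shift the streams of the others.
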