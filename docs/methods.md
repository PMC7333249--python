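# Methods

This note documents the models implemented in `nspec`, the synthetic data
they are exercised on, and the numerical and design choices made where the
problem left them open. It states no empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## The estimation problem

The response is leaf nitrogen concentration (mass % N in leaf tissue); the
predictors are canopy reflectance spectra on a 400–950 nm grid at 1 nm
(551 bands). The physics gives the workflow its shape: chlorophyll —
which tracks N — absorbs blue (~450 nm) and red (~670 nm) light, so
visible reflectance falls as N rises; canopy structure (biomass, leaf
area) scatters near-infrared light, so the NIR plateau rises with N; and
the transition between the two regimes (the red edge, ~680–750 nm)
shifts toward longer wavelengths with increasing chlorophyll. Spectra are
nearly continuous in wavelength, so adjacent bands are strongly collinear
and p (551) exceeds n (a few hundred plots) — the classical chemometrics
regime that motivates latent-variable regression.

## Pipeline stages

### Smoothing

Savitzky–Golay filtering with a second-order polynomial over a five-band
window (interior convolution weights (−3, 12, 17, 12, −3)/35). Edges use
mirror padding by default so the 551-band grid is preserved
(`edge_policy="shrink"` returns only fully windowed bands instead).
Smoothing is applied once, to raw reflectance, before any transform.

### Transforms

*First-derivative reflectance (FDR)*: central differences over 2Δλ at
interior bands, one-sided differences at the two endpoints. The one-sided
endpoint rule is a deliberate choice: it keeps all 551 bands so VIP
indices stay aligned with wavelengths. FDR is exactly invariant to
additive constants and strongly attenuates any smooth additive
background — the mechanism by which derivative spectroscopy suppresses
soil and illumination effects.

*Continuum removal (CR)*: each spectrum is divided by its upper convex
hull, computed over the full analyzed range as a single segment with a
monotone-chain scan (O(p) on the sorted grid). Collinear hull points are
kept as vertices; their quotient is 1 either way. CR output lies in
(0, 1], equals 1 exactly at hull vertices (including both grid
endpoints), and is invariant to positive rescaling of the spectrum.

### Calibration engines

All four engines mean-center the response; MLR/PCR/PLS mean-center the
predictors without autoscaling (bands share reflectance units), while SVR
z-score standardizes them (its kernel is not scale-equivariant).

- **MLR** — least squares via the minimum-norm (pseudoinverse) solution.
  With 551 predictors and ~165 samples the normal equations are singular;
  the minimum-norm fit interpolates the calibration data and any
  degradation appears in validation. This is stated prominently because
  full-spectrum MLR results are only meaningful with that convention.
- **PCR** — SVD of the centered predictor matrix; the response is
  regressed on the leading k orthogonal scores; k minimizes RMSECV.
- **PLS** — NIPALS PLS1. Per component: weight w ∝ X′y normalized to
  unit length, scores t = Xw, x-loading p = X′t/t′t, y-loading
  q = y′t/t′t, then rank-one deflation of X. The response is not
  deflated: for a single response this is algebraically equivalent
  (scores are mutually orthogonal) and simpler. Coefficients over A
  components are B = W(P′W)⁻¹q. The number of latent variables minimizes
  RMSECV.
- **SVR** — ε-insensitive support vector regression with the Gaussian
  kernel exp(−g‖u−v‖²) (scikit-learn's SMO solver); (c, g, ε) minimize
  RMSECV over a Cartesian grid, log-spaced with half-decade steps by
  default (c: 10⁻²…10³, g: 10⁻²…10², ε ∈ {0.01, 0.1, 0.5}) so values
  like g = 3.16 = 10^0.5 are representable.

*Cross-validation.* Leave-one-out is the default for PCR/PLS order
selection. The SVR grid search defaults to seeded 10-fold: a grid search
multiplies the fold cost by the grid size (297 combinations), and k-fold
is the standard chemometrics compromise there; both schemes are available
everywhere via `CVScheme`. RMSECV ties break toward the smallest model
order (parsimony). All engines are deterministic given data, config and
seed.

### VIP selection

VIPⱼ = √(p · Σₐ SSYₐ·(wⱼₐ/‖wₐ‖)² / Σₐ SSYₐ) with SSYₐ = qₐ²·tₐ′tₐ, summed
over the fitted components. The normalization forces mean(VIP²) = 1,
which is why 1.0 is the conventional threshold; the study this package
emulates uses 2.0 to isolate discrete wavelengths, and that is the
pipeline default. Because contiguous bands exceed the threshold together,
above-threshold bands are grouped into maximal contiguous runs and each
run contributes its VIP-argmax band. Note that a derivative feature
produces two VIP lobes flanking its center (the derivative of a bump
vanishes at the bump center), so a planted feature is typically recovered
as a pair of bands a few nm either side of it. VIP is always computed
from the PLS fit of the winning spectral technique, at its selected
order, even when another engine wins overall.

### Evaluation

r² is the squared Pearson correlation of observed and predicted values;
RMSE is in % N; RPD = SD(observed split, n−1 denominator)/RMSE. These
conventions are not arbitrary: they are the unique pair that reproduces
every printed (SD, RMSE, RPD) triplet in the emulated study's summary
tables, whereas 1 − SSE/SST is inconsistent with them. A perfect fit
(RMSE = 0) reports RPD = +∞. Performance classes: r² < 0.50 unacceptable,
0.50 ≤ r² ≤ 0.75 acceptable, > 0.75 excellent; RPD < 1.40 unacceptable,
1.40 ≤ RPD ≤ 2.00 acceptable, > 2.00 excellent — the "acceptable"
interval is closed on both ends, the outer classes strict. A
"coefficient of deviation" diagnostic sometimes quoted alongside these
has no recoverable definition; predicted-vs-observed slope and intercept
are reported instead.

## The synthetic generator

`SimulationConfig` defaults encode the emulated study's conditions:
315 samples split 165/150, leaf N from a truncated normal with parent
mean 3.80 % and SD 1.24 % on [1.06, 6.16] % (rejection sampling; note the
truncation shrinks the realized SD to ≈ 1.10), 60 scans averaged per
sample, and informative centers {525, 573, 710, 780, 875, 924} nm.

Each clean spectrum is built mechanistically (phenomenologically — not a
radiative-transfer model, whose inversion is famously ill-posed and out
of scope here):

- visible baseline 0.15 minus chlorophyll Gaussians at 450 nm (σ 60) and
  670 nm (σ 45) whose depth grows linearly with leaf N, leaving a green
  peak near 550 nm;
- a logistic red edge (width 8 nm) whose inflection moves 708 → 712 nm
  across the N range, blending into a NIR plateau at 0.34–0.40 that
  rises with N;
- narrow Gaussian features (σ 5 nm, amplitude up to 0.05) at the
  informative centers, absorbing (deepening with N) in the visible and
  additive in the red edge/NIR, so wavelength selection has a known
  ground truth. With noise, drift and jitter at zero the construction is
  monotone in N at every visible band (non-increasing) and every NIR
  band (non-decreasing) — a property the tests verify exactly.

Three stochastic layers sit on top, each on its own seeded stream:

1. **Structural scatter** (`structure_jitter_sd`, default 0.30 % N): the
   spectrum is evaluated at a jittered N proxy, modelling the imperfect
   coupling between leaf N and the optically expressed canopy state.
   This floor is irreducible by any calibration model; without it,
   synthetic validation statistics are unrealistically near-perfect and
   full-spectrum models outrun reduced-wavelength refits by margins field
   data never show.
2. **Smooth additive background** (`drift_amplitude`, default 0.02
   reflectance): a random cosine/sine series of 60 harmonics with
   amplitudes falling as 1/j, normalized to the given
   per-band SD. It is smooth (shortest period ≈ 18 nm), so the
   derivative transform attenuates it strongly, but rich enough
   (~120 effective dimensions against ~165 calibration samples) that
   raw-domain models cannot simply project it out. This is the term that
   makes the derivative transform's advantage demonstrable; a low-order
   polynomial was tried first and rejected because any nuisance of
   3–5 dimensions is annihilated exactly by a 20-component model.
3. **Instrument noise** (`noise_sd`, default 0.004 reflectance per scan,
   an ASD-class figure): white noise whose averaging over
   `scans_per_sample` scans is realized as a single draw with SD
   noise_sd/√scans — identical in distribution, and sharing the
   underlying standard-normal field across scan counts so the √n
   variance reduction is exact under a common seed.

Reflectance is clipped to [10⁻³, 1−10⁻³].

*What the generator does not emulate.* Real spectra carry multiplicative
scatter (illumination geometry), water-vapor features, soil-line
structure, and a nonlinear, saturating N response; none are modelled.
One visible consequence: the continuum-removed correlation profile here
is predominantly negative, because the hull quotient cancels N-trends
shared between a band and its nearby hull vertex — field studies report
positive CR correlations across the visible/NIR, which this construction
does not reproduce. Passing tests therefore demonstrate the correctness
of the algorithms and the qualitative transform ordering
(derivative ≥ raw for PLS validation RPD), not field-level performance;
absolute synthetic metrics are optimistic relative to real campaigns.

Another known artefact: with the default grid on 551 standardized
derivative bands, many NIR bands are derivative-flat (noise only), the
pairwise distances concentrate, and the RBF kernel saturates at the
grid's smallest g — full-spectrum SVR then degenerates toward a constant
predictor. On the selected effective wavelengths (a handful of
informative bands) the same grid works well, which is where the emulated
study tuned it. Extending the g grid below 10⁻² would relieve this at
the cost of departing from the documented default.

## Numerical choices

- Grid regularity is enforced (relative tolerance 10⁻⁹) before
  differentiation and smoothing; uneven grids raise `GridError`.
- The upper hull keeps collinear vertices (strict-inequality pops), and
  the CR quotient is clamped to ≤ 1 against last-ulp excursions; hull
  vertices are set to exactly 1.
- NIPALS stops early when the residual covariance or score norm vanishes
  (rank-deficient data); requested orders shrink accordingly.
- PCR/PLS cross-validation reuses one decomposition per fold for all
  candidate orders (scores are orthogonal, so per-component coefficients
  are independent), keeping leave-one-out at 551 bands inexpensive.
- RMSECV tie-break: the smallest order among minima.
- `fit_pcr(..., n_components=...)`/`fit_pls(..., n_lv=...)` bypass CV for
  a fixed order — used for the full-rank equivalence checks
  (PCR = PLS = MLR predictions at full rank, verified to 10⁻⁸ relative).
- Study sizes follow the emulated campaign (n = 315, split 165/150); the
  test suite's miniature pipeline runs use n = 90 with 5-fold CV, which
  preserves every code path at a fraction of the cost.

## Known limitations

- PLS1 only (single response); no PLS2, kernel PLS, or regularized
  alternatives.
- No scatter correction (SNV/MSC) or wavelet denoising; smoothing is
  Savitzky–Golay only.
- Wavelength selection is VIP-with-runs only (no CARS/SPA/interval-PLS).
- The synthetic red-edge/feature construction makes the derivative
  signal nearly rank-one in N, so the selected number of latent
  variables on synthetic data is typically 1–5 — smaller than the ~7
  reported on field data, whose N signal is spread across more
  independent spectral modes.
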