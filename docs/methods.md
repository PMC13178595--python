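# Methods

## Model

The measured tissue fluorescence spectrum F_m(λ) is modelled as a nonnegative
linear mixture of fluorophore emission components, multiplicatively distorted
by tissue optical properties. The distortion is corrected by dividing by a
power of the co-registered diffuse reflectance spectrum,

    F_c(λ) = F_m(λ) / R(λ)^α,  α ∈ [0, 1],

and the adaptive fit estimates α per measurement jointly with the unmixing:

    min_{α, C, μ, σ}  Σ_λ [ F_m(λ)/R(λ)^α − Σᵢ Cᵢ bᵢ(λ; μᵢ, σᵢ) ]²

with α ∈ [0, 1], Cᵢ ≥ 0 and, for Gaussian-modelled components, (μᵢ, σᵢ)
confined to narrow boxes (protein-bound FMN 495±1 / 15±1 nm, lipopigments
590±1 / 10±1 nm, PpIX 637±1 / 6.25±0.75 nm and 619±1 / 8.25±0.75 nm). The
boxes prevent the flexible Gaussian shapes from absorbing arbitrary spectral
structure (overfitting). α = 1 corresponds to the absorption-dominated linear
correction, α = 0 to no correction; a single phantom-calibrated α per
excitation wavelength reproduces the fixed-exponent baseline method.

Assumptions: the distortion is a smooth multiplicative function of the same
reflectance spectrum observed by the probe; emission shapes are constant
within a measurement; amplitudes are nonnegative. Only *relative* fractions
cᵢ = Cᵢ/ΣCᵢ are reported — the measured spectrum is normalized to unit
integral over the fit range before fitting, so absolute concentrations are
out of reach by construction.

The corrected data term F_m/R^α is deliberately **not** re-normalized inside
the objective: re-normalizing would make the data term's scale depend
nonlinearly on α and couple the normalization into the estimate. Corrected
spectra are normalized by their integral only for display.

## Solver

Variable projection: for any fixed (α, μ, σ) the amplitudes solve a
nonnegative linear least-squares problem (scipy's NNLS), so the nonlinear
search runs only over α and the Gaussian shape parameters, via bounded
trust-region least squares from multiple seeded starting points (default 8:
the box midpoint plus 7 uniform draws). For libraries without Gaussian
components the search is one-dimensional in α and is polished with a bounded
scalar minimization. Convergence uses a relative cost-change tolerance
derived from the residual-change criterion (default 1e-6) with an iteration
cap of 10⁴; the `converged` flag is always surfaced. Bounds are closed boxes
([0,1], [0,∞)) — strict inequalities cannot be enforced numerically — and
boundary solutions are reported as-is.

Degenerate input: if R is constant over the fit range (relative spread
≤ 1e-6), R^α is a constant absorbed by normalization and α is structurally
unidentifiable; the fit returns α = 0 with `alpha_identifiable=False` rather
than an arbitrary interior value.

Independent verification: `alpha_profile_oracle` solves the inner NNLS on a
dense α grid (Gaussian shapes frozen at box centers) and must agree with the
joint fit's α; `multistart_robustness` re-runs the fit from many random
feasible starts and reports the dispersion of (α, fractions) among runs whose
absolute residual integral is below 5% of the (unit) integral of F_m.

## Spectral reduction

Raw interleaved frames are reduced per the acquisition protocol: per-pair
background subtraction; repeat averaging after robust anomaly screening
(median/MAD z-score on frame integrals, threshold 5 — an automatable stand-in
for visual motion-artifact QC); division by integration time and laser power
(fluorescence, → counts·s⁻¹·mW⁻¹); ratio to the white-standard acquisition
times its certified reflectivity (reflectance, dimensionless). Calibrated
reflectance is clamped to [1e-4, 1] with a logged warning — the correction
divides by R^α, so R must stay bounded away from zero. Integrals use the
trapezoidal rule on the native grid; wavelength lookups (e.g. the 510 nm
repeatability point) use the nearest grid point within ±1 nm. Fit ranges:
480–620 nm for the phantom library, 480–645 nm for the liver library.
Measured basis spectra are normalized to unit trapezoidal integral over the
fit range when the design matrix is assembled, which makes amplitudes
comparable across components and the fractions shape-weighted.

## Synthetic data

The study's phantom spectra are not public, so the simulator stands in for
them with full ground truth.

*Phantom suite.* Seven phantoms follow the published composition template:
four FAD+TiO2 phantoms and three NADH+TiO2 phantoms with varying mixes of
two Acid-Red-like absorbers (AR1-like: single 555/30 nm band, deoxy-Hb-like;
AR14-like: 542/12 + 577/10 nm double band, oxy-Hb-like; peak-normalized
shapes — the real extinctions are plotted but not tabulated in the
literature, and only the qualitative structure matters for exercising the
correction). Reflectance uses a smooth attenuation ansatz
R = 0.9·exp(−L0·μ_a^1.5/√(μ_a+μ_s')) with μ_s' = a(λ/500)⁻¹; it falls with
absorption, rises with scattering, and L0 = 8 puts the deepest suite
absorption valley at ~10× attenuation. Fluorescence is the exact inverse
image of the correction model, F_m = (Σ Cᵢ bᵢ)·R^α_true, so noiseless
instances are exactly invertible — recovery tests are closed under the
generator's own bases. The per-phantom exponent α_true ~ U[0.3, 0.9]: a
single shared exponent would make the fixed-α calibration optimal by
construction and hide the adaptive method's advantage. Synthetic emission
bases (NADH-like 470/38 nm, FAD-like 528/33 nm, TiO2-like 500/60 nm,
Gaussian) are labelled synthetic throughout; at the 375 nm tag the NADH
amplitude is boosted 5× (shorter-wavelength excitation is strongly
NADH-preferential), the 405 nm tag is balanced.

*Noise.* Each acquisition carries i.i.d. multiplicative Gaussian noise of
relative SD `noise_cv` (default 2%, the repeat-to-repeat repeatability
level) plus an additive dark floor in raw count frames (mean 50, SD 2
counts). Poisson shot noise is deliberately omitted so outputs are
bit-reproducible at a fixed seed. The suite emits the *protocol-reduced*
measurement — the mean of K = 5 noisy repeats of both F_m and R — because
that is the spectrum the acquisition protocol actually fits; its effective
noise is therefore 2%/√5. Raw bundles (2N reflectance + 4K fluorescence
frames) are available separately for pipeline and repeatability tests, and
the per-repeat coefficient of variation at 510 nm reproduces the 2% level.

What the simulator does **not** emulate: instrument spectral response,
probe-pressure effects, photobleaching, wavelength-correlated noise, and the
difference between the generator's Gaussian bases and real measured emission
shapes. Passing recovery tests therefore demonstrates correctness of the
estimation machinery under the stated noise model, not performance on real
tissue spectra.

*Perfusion timecourse.* Three phases with linearly drifting true fractions:
HOPE (120 min, weak preservation-solution absorption, slow FAD rise),
warm ischemia (60 min, no perfusion absorber, lipopigments 1% → 3%), NMP
(120 min, blood-strength absorption, FAD 40% → 60% with NADH falling).
Fraction knots sum to 1 exactly; the absorber regime and generating exponent
switch at phase boundaries. Trend analysis fits unweighted per-phase OLS
lines to each fraction and to the redox ratio c_FAD/(c_FAD+c_NADH); phases
with fewer than two points yield intercept-only records.

## Detection and quantification metrics

A fluorophore is called present when its recovered fraction exceeds a
configurable threshold, default 0.01: fractions of 1–3% (e.g. lipopigments
during ischemia) are meaningful detections, while numerically-zero NNLS
amplitudes are not. Sensitivity = TP/(TP+FN), specificity = TN/(TN+FP) over
(phantom, fluorophore) presence calls; undefined ratios (zero denominator)
are reported as not-applicable rather than 0. MAE = (1/N)Σ|c_meas − c_true|
over all pairs (N = 21 for the suite). Metrics are stored at full precision;
one-decimal rounding happens only in formatted reports.

## Problem sizes and defaults

Suite evaluations run 7 phantoms × 2 excitation tags; repeatability
statistics average 50 seeds × 7 phantoms × 2 tags; multistart verification
uses 100 starts (dispersion < 1e-3 on well-posed instances); the α-grid
oracle uses step 1e-3. A full suite evaluation of all three methods takes a
few seconds on one CPU; the liver-library joint fit (9 nonlinear parameters)
takes ~0.1–0.3 s per spectrum.

## Known limitations

* The exponent family F_m/R^α is empirical; measurements whose distortion is
  not well captured by a single power of R will leave structured residuals.
* With heavily overlapping emission shapes, NNLS can leak ~1% of a truly
  absent component's fraction under noise; near the 1% detection threshold
  this occasionally costs a specificity point on a suite replicate.
* Absolute concentrations, dual-excitation fusion and recovery of absorber
  concentrations or oxygenation from reflectance are out of scope.
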