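# fluorocorr

Quantification of endogenous tissue fluorophores (NADH, FAD, protein-bound
FMN, lipopigments, protoporphyrin IX) from paired fluorescence and diffuse
reflectance spectra, with an **adaptive reflectance-based correction** for
tissue optical properties.

## The problem

A fluorescence emission spectrum measured on tissue, F_m(λ), is distorted by
wavelength-dependent absorption (chiefly hemoglobin) and scattering. Fitting
the plain linear mixture model

    F_m(λ) = Σᵢ Cᵢ · fᵢ(λ)

to a distorted spectrum misquantifies the relative fluorophore fractions
cᵢ = Cᵢ / ΣCᵢ — a serious problem for applications such as machine-perfusion
monitoring of donor liver grafts, where the organ swings between blood
perfusion, ischemia and transparent preservation solution, so its optical
properties vary enormously within hours.

## The method

The correction family divides by a power of the co-registered diffuse
reflectance spectrum R(λ):

    F_c(λ) = F_m(λ) / R(λ)^α,   α ∈ [0, 1]

* α = 1 — the absorption-dominated linear (Kim-style) correction;
* α fixed per excitation wavelength, calibrated once on phantoms — the
  Valdes-style correction;
* **adaptive** — α is fitted *per measurement*, jointly with a nonnegative
  unmixing of the corrected spectrum:

      min over α, Cᵢ, μᵢ, σᵢ of
      ‖ F_m(λ)/R(λ)^α − Σᵢ Cᵢ · bᵢ(λ; μᵢ, σᵢ) ‖²
      subject to 0 ≤ α ≤ 1,  Cᵢ ≥ 0,  (μᵢ, σᵢ) inside box constraints

  where bᵢ are fixed measured emission bases (NADH, FAD) or box-constrained
  Gaussian components (FMN, lipopigments, PpIX 620/636). The solver uses
  variable projection (inner NNLS, outer bounded least squares, seeded
  multi-start) plus a brute-force α-grid oracle for independent verification.

Because the study's original spectra are not public, the package ships a
tissue-phantom simulator (7-phantom suite with blood-mimicking absorbers,
TiO2 scattering, per-phantom distortion exponent, 2% repeat noise) and a
liver-perfusion timecourse generator, both with full ground truth, and
detection/quantification metrics (sensitivity, specificity, MAE) plus
NADH/FAD redox-ratio trend analysis.

## Worked example

```python
import fluorocorr as fc

# simulate one phantom measurement and fit it three ways
suite = fc.generate_phantom_suite(seed=0)
rec = suite[1]                                  # phantom 2, 375 nm tag
library = fc.default_phantom_library()
model = fc.ReflectanceCorrection(rec.fluorescence, rec.reflectance, library)
res = model.fit("adaptive")
print(res.summary())
print("truth:", rec.truth_fractions, " true alpha:", round(rec.spec.true_alpha, 3))
```

prints

```
Reflectance-corrected unmixing fit
==========================================
method:              adaptive
alpha:               0.4591
mse:                 1.4132e-08
n wavelengths:       141
converged:           True
------------------------------------------
component          amplitude    fraction
NADH               0.0003642      0.0002
FAD                    1.137      0.7192
TiO2                  0.4435      0.2806
truth: {'NADH': 0.0, 'FAD': 0.72, 'TiO2': 0.28}  true alpha: 0.462
```

The fitted exponent α ≈ 0.46 matches the phantom's generating distortion, and
the recovered relative fractions agree with the ground truth to well under a
percentage point; the Kim (α = 1) fit on the same pair misassigns a large
fraction to an absent fluorophore (`model.fit("kim")`).

A command-line surface wraps the same functionality:

```
fluorocorr simulate --seed 0 --out suite/
fluorocorr calibrate suite/ --out cal.json
fluorocorr evaluate suite/ --out report.tsv
fluorocorr monitor timecourse/ --out monitor.tsv
```

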