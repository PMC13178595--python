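"""Tissue-mimicking phantom and perfusion-timecourse simulator.

Generates synthetic measurement pairs (fluorescence F_m, diffuse reflectance
R) with full ground truth, emulating a liquid-phantom suite built from one
dominant fluorophore (FAD or NADH) plus TiO2 scatterer and blood-mimicking
Acid Red absorbers, and a liver machine-perfusion timecourse with drifting
NADH/FAD fractions.

Forward model
-------------
Reflectance uses a smooth semi-infinite attenuation ansatz::

    mu_a(lam)  = sum_k conc_k * eps_k(lam)        (absorbers)
    mu_s'(lam) = a * (lam / 500)**(-b)            (scatterer)
    R(lam)     = rho0 * exp(-L0 * mu_a**1.5 / sqrt(mu_a + mu_s'))

The correction method consumes R as data, so only the realism of its
spectral structure matters, not radiometric accuracy.  Fluorescence is the
exact inverse image of the correction model::

    F_m(lam) = (sum_i C_i * b_i(lam)) * R(lam)**alpha_true

optionally degraded by i.i.d. multiplicative Gaussian noise of relative SD
``noise_cv`` (matching ~2% repeat-to-repeat variability).  Noiseless outputs
are exactly invertible by the adaptive fit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .basis import BasisLibrary, default_liver_library, default_phantom_library
from .spectra import AcquisitionProtocol, RawAcquisitionSet, Spectrum, validate_grid

DEFAULT_GRID = np.arange(460.0, 661.0, 1.0)
DEFAULT_NOISE_CV = 0.02

#: relative NADH brightness boost at the 375 nm tag (fluorescence at the
#: shorter excitation is almost entirely NADH); the 405 nm tag is balanced.
EXCITATION_NADH_WEIGHT = {"375": 5.0, "405": 1.0}

#: photon budget used when emitting raw count frames
RAW_BRIGHTNESS = 5.0e5  # counts / s / mW at unit model amplitude
DARK_MEAN = 50.0        # counts per frame
DARK_SD = 2.0


@dataclass(frozen=True)
class AbsorberSpec:
    """Blood-mimicking dye: named extinction shape at a mass concentration."""

    name: str       # "AR1_like" or "AR14_like"
    concentration_g_per_L: float


@dataclass(frozen=True)
class ScatteringSpec:
    """Reduced scattering mu_s'(lam) = a * (lam/500)**(-b), a in 1/cm at 500 nm."""

    a: float = 10.0
    b: float = 1.0

    def __post_init__(self):
        if self.a <= 0 or self.b < 0:
            raise ValueError("need a > 0 and b >= 0")

    def mu_s_prime(self, grid: np.ndarray) -> np.ndarray:
        return self.a * (np.asarray(grid) / 500.0) ** (-self.b)


@dataclass
class PhantomSpec:
    """Ground-truth description of one synthetic phantom."""

    id: str
    absorbers: list
    scattering: ScatteringSpec
    base_fractions: dict          # fluorophore -> fraction before excitation weighting
    true_alpha: float
    noise_cv: float = DEFAULT_NOISE_CV

    def __post_init__(self):
        fr = np.array(list(self.base_fractions.values()))
        if np.any(fr < 0) or abs(fr.sum() - 1.0) > 1e-9:
            raise ValueError("base fractions must be nonnegative and sum to 1")
        if not (0.0 <= self.true_alpha <= 1.0):
            raise ValueError("true alpha must lie in [0, 1]")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be nonnegative")

    def true_fractions(self, excitation_tag: str) -> dict:
        """Effective fractions after excitation-dependent brightness weighting."""
        w = EXCITATION_NADH_WEIGHT.get(str(excitation_tag), 1.0)
        amps = {k: v * (w if k == "NADH" else 1.0)
                for k, v in self.base_fractions.items()}
        total = sum(amps.values())
        return {k: v / total for k, v in amps.items()}


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------

def make_absorber_extinction(name: str, grid: np.ndarray) -> Spectrum:
    """Peak-normalized extinction shape for the packaged absorber set.

    AR1_like: single broad band at 555 nm (deoxy-hemoglobin-like);
    AR14_like: double band at 542/577 nm (oxy-hemoglobin-like).
    """
    grid = validate_grid(grid)
    if name == "AR1_like":
        vals = np.exp(-((grid - 555.0) ** 2) / (2 * 30.0 ** 2))
    elif name == "AR14_like":
        vals = (np.exp(-((grid - 542.0) ** 2) / (2 * 12.0 ** 2))
                + 0.9 * np.exp(-((grid - 577.0) ** 2) / (2 * 10.0 ** 2)))
    else:
        raise ValueError(f"unknown absorber {name!r} (expected AR1_like or AR14_like)")
    vals = vals / vals.max()
    return Spectrum(grid, vals, "basis", {"absorber": name})


def simulate_reflectance(phantom: PhantomSpec, grid: np.ndarray | None = None,
                         rho0: float = 0.9, L0: float = 8.0) -> Spectrum:
    """Smooth reflectance spectrum in (0, 1].

    Attenuation scales like mu_a**1.5 / sqrt(mu_a + mu_s'), mirroring the
    diffusion-regime behaviour that reflectance falls with absorption and
    rises with scattering; L0 sets the depth of the absorption valley
    (~10x at blood-like absorber strength).
    """
    grid = validate_grid(DEFAULT_GRID if grid is None else grid)
    mu_a = np.zeros_like(grid)
    for ab in phantom.absorbers:
        mu_a += ab.concentration_g_per_L * make_absorber_extinction(ab.name, grid).values
    mu_s = phantom.scattering.mu_s_prime(grid)
    r = rho0 * np.exp(-L0 * mu_a ** 1.5 / np.sqrt(mu_a + mu_s))
    return Spectrum(grid, r, "reflectance", {"phantom": phantom.id})


def simulate_fluorescence(phantom: PhantomSpec, library: BasisLibrary,
                          grid: np.ndarray | None = None,
                          excitation_tag: str = "375",
                          with_noise: bool = False,
                          rng: np.random.Generator | None = None,
                          gaussian_params: dict | None = None) -> Spectrum:
    """F_m = (sum_i C_i b_i) * R**alpha_true, optionally with multiplicative noise."""
    grid = validate_grid(DEFAULT_GRID if grid is None else grid)
    fractions = phantom.true_fractions(excitation_tag)
    names = library.component_names
    missing = set(fractions) - set(names)
    if missing:
        raise ValueError(f"fraction keys not in library: {sorted(missing)}")
    a = library.design_matrix(grid, gaussian_params)
    c = np.array([fractions.get(n, 0.0) for n in names])
    ideal = a @ c
    r = simulate_reflectance(phantom, grid)
    fm = ideal * r.values ** phantom.true_alpha
    if with_noise:
        rng = rng or np.random.default_rng(0)
        fm = fm * (1.0 + rng.normal(0.0, phantom.noise_cv, size=fm.shape))
        fm = np.maximum(fm, 0.0)
    return Spectrum(grid, fm, "fluorescence",
                    {"phantom": phantom.id, "excitation_nm": excitation_tag})


# ---------------------------------------------------------------------------
# the seven-phantom suite
# ---------------------------------------------------------------------------

# (dominant fluorophore, [(absorber, g/L), ...], TiO2 mg, dominant fraction)
_SUITE_TEMPLATE = (
    ("FAD", (("AR1_like", 0.50),), 236, 0.80),
    ("FAD", (("AR1_like", 0.50), ("AR14_like", 0.46)), 214, 0.72),
    ("FAD", (("AR1_like", 0.28), ("AR14_like", 0.21)), 248, 0.75),
    ("FAD", (("AR14_like", 0.42),), 224, 0.68),
    ("NADH", (("AR1_like", 0.58),), 229, 0.78),
    ("NADH", (("AR1_like", 0.28), ("AR14_like", 0.21)), 244, 0.70),
    ("NADH", (("AR14_like", 0.42),), 250, 0.74),
)

CANDIDATE_FLUOROPHORES = ("NADH", "FAD", "TiO2")


@dataclass
class SuiteRecord:
    """One simulated measurement: phantom + excitation tag + spectra + truth."""

    spec: PhantomSpec
    excitation_tag: str
    fluorescence: Spectrum
    reflectance: Spectrum
    truth_fractions: dict


def make_suite_phantoms(seed: int = 0,
                        noise_cv: float = DEFAULT_NOISE_CV) -> list:
    """The seven PhantomSpec objects with seeded per-phantom true alpha.

    Each phantom carries one dominant fluorophore (FAD for n. 1-4, NADH for
    n. 5-7) plus the broad TiO2 emission; the absorber mixes follow the
    published composition template.  The true correction exponent is drawn
    per phantom from U[0.3, 0.9] so that no single shared alpha is optimal.
    """
    rng = np.random.default_rng(seed)
    alphas = rng.uniform(0.3, 0.9, size=len(_SUITE_TEMPLATE))
    phantoms = []
    for i, (fluor, absorbers, tio2_mg, frac) in enumerate(_SUITE_TEMPLATE):
        base = {n: 0.0 for n in CANDIDATE_FLUOROPHORES}
        base[fluor] = frac
        base["TiO2"] = 1.0 - frac
        phantoms.append(PhantomSpec(
            id=f"phantom_{i + 1}",
            absorbers=[AbsorberSpec(n, c) for n, c in absorbers],
            scattering=ScatteringSpec(a=10.0 * tio2_mg / 236.0, b=1.0),
            base_fractions=base,
            true_alpha=float(alphas[i]),
            noise_cv=noise_cv,
        ))
    return phantoms


def generate_phantom_suite(seed: int = 0, noise_cv: float = DEFAULT_NOISE_CV,
                           excitations=("375", "405"),
                           grid: np.ndarray | None = None,
                           library: BasisLibrary | None = None,
                           with_noise: bool = True,
                           n_repeats: int = 5) -> list:
    """Simulated (F_m, R) pairs with truth for all phantoms and excitation tags.

    ``noise_cv`` is the per-repeat repeatability (coefficient of variation of a
    single acquisition).  The emitted spectra are the protocol-reduced
    measurements — the mean of ``n_repeats`` noisy repeats, matching the
    K = 5 averaging of the acquisition sequence — so their effective noise is
    noise_cv / sqrt(n_repeats).  Set ``n_repeats=1`` for single-shot spectra.
    """
    grid = validate_grid(DEFAULT_GRID if grid is None else grid)
    library = library or default_phantom_library(grid)
    phantoms = make_suite_phantoms(seed, noise_cv)
    rng = np.random.default_rng(seed + 1)
    records = []
    for tag in excitations:
        for ph in phantoms:
            if with_noise and noise_cv > 0:
                reps = [simulate_fluorescence(ph, library, grid, tag,
                                              with_noise=True, rng=rng).values
                        for _ in range(n_repeats)]
                fm_vals = np.mean(reps, axis=0)
                fm = Spectrum(grid, fm_vals, "fluorescence",
                              {"phantom": ph.id, "excitation_nm": tag,
                               "n_repeats": n_repeats})
                r0 = simulate_reflectance(ph, grid)
                r_reps = [r0.values * (1.0 + rng.normal(0.0, noise_cv, grid.shape))
                          for _ in range(n_repeats)]
                r = r0.copy(values=np.clip(np.mean(r_reps, axis=0), 1e-4, 1.0))
            else:
                fm = simulate_fluorescence(ph, library, grid, tag,
                                           with_noise=False)
                r = simulate_reflectance(ph, grid)
            records.append(SuiteRecord(ph, str(tag), fm, r,
                                       ph.true_fractions(tag)))
    return records


# ---------------------------------------------------------------------------
# raw acquisition bundles
# ---------------------------------------------------------------------------

def _lamp_spectrum(grid: np.ndarray) -> np.ndarray:
    """Smooth broadband lamp shape in counts/s."""
    return 1.0e4 * np.exp(-((grid - 560.0) ** 2) / (2 * 150.0 ** 2))


def _count_frame(grid, rate, T, rng, noise_cv) -> Spectrum:
    counts = rate * T
    if noise_cv > 0:
        counts = counts * (1.0 + rng.normal(0.0, noise_cv, size=counts.shape))
    counts = counts + DARK_MEAN + rng.normal(0.0, DARK_SD, size=counts.shape)
    return Spectrum(grid, counts, "raw")


def _background_frame(grid, rng) -> Spectrum:
    vals = DARK_MEAN + rng.normal(0.0, DARK_SD, size=grid.shape)
    return Spectrum(grid, vals, "raw")


def generate_raw_acquisition(phantom: PhantomSpec, library: BasisLibrary,
                             protocol: AcquisitionProtocol | None = None,
                             seed: int = 0,
                             grid: np.ndarray | None = None,
                             excitations=("375", "405")) -> dict:
    """Emit the interleaved raw frame bundle for one phantom.

    Returns a dict with a "white" RawAcquisitionSet (N signal/background
    reflectance pairs) and one set of K signal/background pairs per laser tag
    (2N + 4K frames total).  The multiplicative noise model matches the
    phantom's noise_cv; backgrounds carry the additive dark floor only.
    Reducing the bundle through the spectral pipeline reproduces the
    noiseless spectra within the noise budget.
    """
    grid = validate_grid(DEFAULT_GRID if grid is None else grid)
    protocol = protocol or AcquisitionProtocol()
    rng = np.random.default_rng(seed)
    T = protocol.integration_time_s
    lamp = _lamp_spectrum(grid)
    r_true = simulate_reflectance(phantom, grid).values

    bundle = {}
    sig, bg = [], []
    for _ in range(protocol.n_reflectance):
        sig.append(_count_frame(grid, lamp * r_true, T, rng, phantom.noise_cv))
        bg.append(_background_frame(grid, rng))
    bundle["white"] = RawAcquisitionSet("white", sig, bg)

    for tag in excitations:
        fm_rate = simulate_fluorescence(phantom, library, grid, tag,
                                        with_noise=False).values * RAW_BRIGHTNESS
        power = protocol.excitation_powers_mW.get(str(tag), 1.0)
        sig, bg = [], []
        for _ in range(protocol.n_fluor_repeats):
            sig.append(_count_frame(grid, fm_rate * power, T, rng, phantom.noise_cv))
            bg.append(_background_frame(grid, rng))
        bundle[str(tag)] = RawAcquisitionSet(str(tag), sig, bg)
    return bundle


def generate_standard_acquisition(protocol: AcquisitionProtocol | None = None,
                                  seed: int = 0,
                                  grid: np.ndarray | None = None,
                                  reflectivity: float = 0.99,
                                  noise_cv: float = 0.002) -> RawAcquisitionSet:
    """Raw frames of the certified white standard under the same protocol."""
    grid = validate_grid(DEFAULT_GRID if grid is None else grid)
    protocol = protocol or AcquisitionProtocol()
    rng = np.random.default_rng(seed)
    T = protocol.integration_time_s
    lamp = _lamp_spectrum(grid)
    sig, bg = [], []
    for _ in range(protocol.n_reflectance):
        sig.append(_count_frame(grid, lamp * reflectivity, T, rng, noise_cv))
        bg.append(_background_frame(grid, rng))
    return RawAcquisitionSet("white", sig, bg)


# ---------------------------------------------------------------------------
# perfusion timecourse
# ---------------------------------------------------------------------------

#: absorber/scattering regimes during the perfusion protocol
ABSORBER_REGIMES = {
    "preservation_solution": {"absorbers": [AbsorberSpec("AR14_like", 0.05)],
                              "alpha": 0.35},
    "none": {"absorbers": [], "alpha": 0.30},
    "blood": {"absorbers": [AbsorberSpec("AR1_like", 0.30),
                            AbsorberSpec("AR14_like", 0.30)],
              "alpha": 0.75},
}


@dataclass(frozen=True)
class PhaseSpec:
    name: str
    duration_min: float
    start_fractions: dict
    end_fractions: dict
    absorber_regime: str = "none"

    def __post_init__(self):
        for knot in (self.start_fractions, self.end_fractions):
            total = sum(knot.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"phase {self.name!r}: fractions sum to {total}, expected 1")
        if self.absorber_regime not in ABSORBER_REGIMES:
            raise ValueError(f"unknown absorber regime {self.absorber_regime!r}")


@dataclass
class TimecourseSpec:
    phases: list
    sampling_interval_min: float = 10.0
    noise_cv: float = DEFAULT_NOISE_CV
    seed: int = 0


def default_timecourse_spec() -> TimecourseSpec:
    """HOPE / warm-ischemia / NMP protocol with drifting fluorophore fractions.

    NMP carries the headline dynamics: FAD rising 0.40 -> 0.60 with NADH
    falling, under blood-strength absorption; warm ischemia shows the
    lipopigment rise 0.01 -> 0.03 with no perfusion absorber.
    """
    hope_start = {"NADH": 0.45, "FAD": 0.40, "FMN_bound": 0.06,
                  "lipopigments": 0.01, "PpIX_636": 0.05, "PpIX_620": 0.03}
    hope_end = {"NADH": 0.40, "FAD": 0.45, "FMN_bound": 0.06,
                "lipopigments": 0.01, "PpIX_636": 0.05, "PpIX_620": 0.03}
    wi_start = {"NADH": 0.42, "FAD": 0.43, "FMN_bound": 0.06,
                "lipopigments": 0.01, "PpIX_636": 0.05, "PpIX_620": 0.03}
    wi_end = {"NADH": 0.40, "FAD": 0.43, "FMN_bound": 0.06,
              "lipopigments": 0.03, "PpIX_636": 0.05, "PpIX_620": 0.03}
    nmp_start = {"NADH": 0.48, "FAD": 0.40, "FMN_bound": 0.05,
                 "lipopigments": 0.02, "PpIX_636": 0.03, "PpIX_620": 0.02}
    nmp_end = {"NADH": 0.30, "FAD": 0.60, "FMN_bound": 0.04,
               "lipopigments": 0.02, "PpIX_636": 0.02, "PpIX_620": 0.02}
    return TimecourseSpec(phases=[
        PhaseSpec("HOPE", 120.0, hope_start, hope_end, "preservation_solution"),
        PhaseSpec("warm_ischemia", 60.0, wi_start, wi_end, "none"),
        PhaseSpec("NMP", 120.0, nmp_start, nmp_end, "blood"),
    ])


@dataclass
class TimePoint:
    t_min: float
    phase: str
    fluorescence: Spectrum
    reflectance: Spectrum
    truth_fractions: dict
    true_alpha: float


def generate_timecourse(spec: TimecourseSpec | None = None,
                        library: BasisLibrary | None = None,
                        grid: np.ndarray | None = None) -> list:
    """Sampled timecourse of (F_m, R) pairs with linearly drifting fractions."""
    spec = spec or default_timecourse_spec()
    grid = validate_grid(np.arange(460.0, 681.0, 1.0) if grid is None else grid)
    library = library or default_liver_library(grid)
    rng = np.random.default_rng(spec.seed)
    points = []
    t0 = 0.0
    for phase in spec.phases:
        regime = ABSORBER_REGIMES[phase.absorber_regime]
        n = max(int(np.floor(phase.duration_min / spec.sampling_interval_min)), 1)
        for k in range(n):
            t = t0 + k * spec.sampling_interval_min
            u = (t - t0) / phase.duration_min
            fractions = {
                key: (1 - u) * phase.start_fractions[key] + u * phase.end_fractions[key]
                for key in phase.start_fractions
            }
            ph = PhantomSpec(
                id=f"{phase.name}_{k}",
                absorbers=list(regime["absorbers"]),
                scattering=ScatteringSpec(a=10.0, b=1.0),
                base_fractions=fractions,
                true_alpha=regime["alpha"],
                noise_cv=spec.noise_cv,
            )
            # liver fractions already include any excitation weighting; use the
            # balanced tag so true_fractions == base_fractions
            fm = simulate_fluorescence(ph, library, grid, "405",
                                       with_noise=spec.noise_cv > 0, rng=rng)
            r = simulate_reflectance(ph, grid)
            points.append(TimePoint(t, phase.name, fm, r, fractions,
                                    ph.true_alpha))
        t0 += phase.duration_min
    return points


def phase_windows(spec: TimecourseSpec | None = None) -> list:
    """(name, start_min, end_min) windows matching generate_timecourse."""
    spec = spec or default_timecourse_spec()
    out, t0 = [], 0.0
    for phase in spec.phases:
        out.append((phase.name, t0, t0 + phase.duration_min))
        t0 += phase.duration_min
    return out


# ---------------------------------------------------------------------------
# on-disk suite layout
# ---------------------------------------------------------------------------

def write_suite(records: list, directory) -> Path:
    from .spectra import write_spectrum

    directory = Path(directory)
    manifest = []
    for rec in records:
        sub = directory / f"{rec.spec.id}_{rec.excitation_tag}"
        sub.mkdir(parents=True, exist_ok=True)
        write_spectrum(rec.fluorescence, sub / "fluorescence.csv")
        write_spectrum(rec.reflectance, sub / "reflectance.csv")
        truth = {
            "fractions": rec.truth_fractions,
            "alpha": rec.spec.true_alpha,
            "composition": {
                "absorbers": [[a.name, a.concentration_g_per_L]
                              for a in rec.spec.absorbers],
                "scattering": {"a": rec.spec.scattering.a,
                               "b": rec.spec.scattering.b},
            },
        }
        (sub / "truth.json").write_text(json.dumps(truth, indent=1))
        manifest.append({"phantom": rec.spec.id,
                         "excitation": rec.excitation_tag,
                         "dir": sub.name})
    mpath = directory / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1))
    return mpath


def read_suite(directory) -> list:
    """Load a written suite as (phantom_id, excitation, Fm, R, truth) dicts."""
    from .spectra import read_spectrum

    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    out = []
    for entry in manifest:
        sub = directory / entry["dir"]
        truth = json.loads((sub / "truth.json").read_text())
        out.append({
            "phantom": entry["phantom"],
            "excitation": entry["excitation"],
            "fluorescence": read_spectrum(sub / "fluorescence.csv"),
            "reflectance": read_spectrum(sub / "reflectance.csv"),
            "truth_fractions": truth["fractions"],
            "true_alpha": truth["alpha"],
        })
    return out
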