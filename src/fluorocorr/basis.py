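"""Fluorophore emission models: measured basis spectra and constrained Gaussians.

Two component families make up a :class:`BasisLibrary`:

* measured bases — fixed emission shapes recorded on single-fluorophore
  phantoms (NADH, FAD, and in liquid phantoms the broad TiO2 emission);
* Gaussian components — fluorophores whose in-tissue emission cannot be
  measured in phantoms (protein-bound FMN, lipopigments, the two PpIX
  emission peaks); their center and width are fitted inside narrow box
  constraints to prevent overfitting.

Measured bases are normalized to unit trapezoidal integral over the fit
range when assembled into a design matrix, so fitted amplitudes are
comparable across components and relative fractions c_i = C_i / sum(C) are
shape-weighted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .spectra import Spectrum, resample_to_grid, validate_grid

SQRT_2PI = float(np.sqrt(2.0 * np.pi))

#: Box constraints for the Gaussian-modelled liver fluorophores
#: (center mu0 +/- mu_tol nm, width sigma0 +/- sigma_tol nm).
LIVER_GAUSSIAN_CONSTRAINTS = (
    ("FMN_bound", 495.0, 1.0, 15.0, 1.0),
    ("lipopigments", 590.0, 1.0, 10.0, 1.0),
    ("PpIX_636", 637.0, 1.0, 6.25, 0.75),
    ("PpIX_620", 619.0, 1.0, 8.25, 0.75),
)

PHANTOM_FIT_RANGE = (480.0, 620.0)
LIVER_FIT_RANGE = (480.0, 645.0)


def gaussian_component(grid: np.ndarray, mu: float, sigma: float) -> Spectrum:
    """Normalized Gaussian density g(lam; mu, sigma) evaluated on ``grid``."""
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    grid = validate_grid(grid)
    vals = np.exp(-((grid - mu) ** 2) / (2.0 * sigma ** 2)) / (sigma * SQRT_2PI)
    return Spectrum(grid, vals, "basis", {"mu": mu, "sigma": sigma})


@dataclass(frozen=True)
class GaussianComponentSpec:
    """Box-constrained Gaussian emission component."""

    name: str
    mu0: float
    mu_tol: float
    sigma0: float
    sigma_tol: float

    def __post_init__(self):
        if self.sigma0 - self.sigma_tol <= 0:
            raise ValueError(f"{self.name}: sigma lower bound must stay positive")
        if self.mu_tol < 0 or self.sigma_tol < 0:
            raise ValueError(f"{self.name}: tolerances must be nonnegative")

    @property
    def mu_bounds(self) -> tuple[float, float]:
        return (self.mu0 - self.mu_tol, self.mu0 + self.mu_tol)

    @property
    def sigma_bounds(self) -> tuple[float, float]:
        return (self.sigma0 - self.sigma_tol, self.sigma0 + self.sigma_tol)

    def contains(self, mu: float, sigma: float) -> bool:
        return (self.mu_bounds[0] <= mu <= self.mu_bounds[1]
                and self.sigma_bounds[0] <= sigma <= self.sigma_bounds[1])


@dataclass
class MeasuredBasis:
    """Fixed measured emission shape for one fluorophore at one excitation."""

    name: str
    excitation_nm: int
    spectrum: Spectrum

    def __post_init__(self):
        if np.any(self.spectrum.values < 0):
            raise ValueError(f"measured basis {self.name!r} has negative values")
        if not np.any(self.spectrum.values > 0):
            raise ValueError(f"measured basis {self.name!r} is identically zero")


@dataclass
class BasisLibrary:
    """Component set for one excitation wavelength plus the fit range."""

    measured: list = field(default_factory=list)
    gaussian: list = field(default_factory=list)
    fit_range: tuple[float, float] = PHANTOM_FIT_RANGE

    def __post_init__(self):
        names = self.component_names
        if len(names) != len(set(names)):
            raise ValueError(f"duplicate component names in library: {names}")
        if not names:
            raise ValueError("library must hold at least one component")
        lo, hi = self.fit_range
        if hi <= lo:
            raise ValueError("fit range must satisfy lo < hi")

    @property
    def component_names(self) -> list:
        return [m.name for m in self.measured] + [g.name for g in self.gaussian]

    @property
    def n_components(self) -> int:
        return len(self.measured) + len(self.gaussian)

    def design_matrix(self, grid: np.ndarray,
                      gaussian_params: dict | None = None) -> np.ndarray:
        """Assemble the [n_lambda x n_components] design matrix on ``grid``.

        Columns follow library order (measured first, then Gaussian).  Measured
        bases are resampled onto ``grid`` and normalized to unit trapezoidal
        integral over the fit range.  ``gaussian_params`` maps component name
        to (mu, sigma); omitted components use (mu0, sigma0).  Parameters
        outside a component's constraint box raise an error naming the
        component and the violated bound.
        """
        grid = validate_grid(grid)
        gaussian_params = gaussian_params or {}
        cols = []
        lo, hi = self.fit_range
        for m in self.measured:
            s = resample_to_grid(m.spectrum, grid)
            area = s.integral((max(lo, grid[0]), min(hi, grid[-1])))
            if area <= 0:
                raise ValueError(f"measured basis {m.name!r} vanishes on the fit range")
            cols.append(s.values / area)
        for g in self.gaussian:
            mu, sigma = gaussian_params.get(g.name, (g.mu0, g.sigma0))
            if not g.contains(mu, sigma):
                raise ValueError(
                    f"component {g.name!r}: (mu={mu}, sigma={sigma}) outside box "
                    f"mu in {g.mu_bounds}, sigma in {g.sigma_bounds}"
                )
            cols.append(gaussian_component(grid, mu, sigma).values)
        return np.column_stack(cols)


# ---------------------------------------------------------------------------
# packaged libraries
# ---------------------------------------------------------------------------

def _gaussian_basis(grid, name, excitation_nm, mu, sigma) -> MeasuredBasis:
    s = gaussian_component(grid, mu, sigma)
    s = s.copy(meta={"synthetic": True, "mu": mu, "sigma": sigma})
    return MeasuredBasis(name, excitation_nm, s)


def default_phantom_library(grid: np.ndarray | None = None,
                            excitation_nm: int = 375) -> BasisLibrary:
    """Synthetic three-component library for the liquid-phantom suite.

    NADH-like, FAD-like and a broad TiO2-like emission are modelled as
    Gaussian shapes (synthetic stand-ins; the real single-fluorophore
    measurements are not distributed with the package).  The exact shapes are
    irrelevant to the correction math — the simulator and the fits share the
    same library, so recovery tests are closed under these shapes.
    """
    if grid is None:
        grid = np.arange(460.0, 661.0, 1.0)
    measured = [
        _gaussian_basis(grid, "NADH", excitation_nm, 470.0, 38.0),
        _gaussian_basis(grid, "FAD", excitation_nm, 528.0, 33.0),
        _gaussian_basis(grid, "TiO2", excitation_nm, 500.0, 60.0),
    ]
    return BasisLibrary(measured=measured, gaussian=[], fit_range=PHANTOM_FIT_RANGE)


def default_liver_library(grid: np.ndarray | None = None,
                          excitation_nm: int = 405) -> BasisLibrary:
    """Six-component liver library: measured NADH/FAD plus four constrained Gaussians.

    The NADH and FAD shapes here are synthetic Gaussian stand-ins for the
    phantom-measured bases; FMN_bound, lipopigments and the two PpIX peaks use
    the packaged box constraints.
    """
    if grid is None:
        grid = np.arange(460.0, 681.0, 1.0)
    measured = [
        _gaussian_basis(grid, "NADH", excitation_nm, 470.0, 38.0),
        _gaussian_basis(grid, "FAD", excitation_nm, 528.0, 33.0),
    ]
    gauss = [GaussianComponentSpec(*row) for row in LIVER_GAUSSIAN_CONSTRAINTS]
    return BasisLibrary(measured=measured, gaussian=gauss, fit_range=LIVER_FIT_RANGE)


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def save_basis_library(library: BasisLibrary, path) -> None:
    """Write a library as JSON with sibling two-column basis spectrum files."""
    from .spectra import write_spectrum

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    doc = {"fit_range": list(library.fit_range), "measured": [], "gaussian": []}
    for m in library.measured:
        fname = f"{path.stem}_{m.name}.tsv"
        write_spectrum(m.spectrum, path.parent / fname)
        doc["measured"].append(
            {"name": m.name, "excitation_nm": m.excitation_nm, "file": fname}
        )
    for g in library.gaussian:
        doc["gaussian"].append(
            {"name": g.name, "mu0": g.mu0, "mu_tol": g.mu_tol,
             "sigma0": g.sigma0, "sigma_tol": g.sigma_tol}
        )
    path.write_text(json.dumps(doc, indent=1))


def load_basis_library(path) -> BasisLibrary:
    from .spectra import read_spectrum

    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed basis library file {path}: {exc}") from exc
    measured = [
        MeasuredBasis(e["name"], int(e["excitation_nm"]),
                      read_spectrum(path.parent / e["file"]).copy(kind="basis"))
        for e in doc.get("measured", [])
    ]
    gauss = [
        GaussianComponentSpec(e["name"], e["mu0"], e["mu_tol"], e["sigma0"], e["sigma_tol"])
        for e in doc.get("gaussian", [])
    ]
    return BasisLibrary(measured=measured, gaussian=gauss,
                        fit_range=tuple(doc["fit_range"]))
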