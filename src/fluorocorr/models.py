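"""Reflectance-based correction of fluorescence spectra with constrained unmixing.

The measured fluorescence spectrum F_m(lam) of tissue is distorted by
wavelength-dependent absorption and scattering.  The correction family used
here divides by a power of the co-registered diffuse reflectance spectrum::

    F_c(lam) = F_m(lam) / R(lam)**alpha,    0 <= alpha <= 1

alpha = 1 is the absorption-dominated (Kim-style) correction, alpha = 0 means
no correction, and a fixed phantom-calibrated alpha per excitation wavelength
is the Valdes-style correction.  The adaptive method fits alpha per
measurement, jointly with a nonnegative unmixing of the corrected spectrum
into fluorophore components::

    min_{alpha, C_i, mu_i, sigma_i}
        || F_m/R**alpha - sum_i C_i * b_i(lam; mu_i, sigma_i) ||^2

subject to alpha in [0, 1], C_i >= 0, and (mu_i, sigma_i) inside the
library's box constraints for Gaussian-modelled components.

The solver uses variable projection: amplitudes are always obtained from a
nonnegative linear least-squares solve at fixed (alpha, mu, sigma), so the
nonlinear search runs only over the shape parameters, from several seeded
starting points.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares, minimize_scalar, nnls

from .basis import BasisLibrary
from .spectra import R_FLOOR, Spectrum, normalize_by_integral, resample_to_grid

#: relative spread below which R is treated as constant over the fit range,
#: making alpha unidentifiable (R**alpha is then absorbed by normalization).
CONSTANT_R_RTOL = 1e-6


@dataclass
class FitOptions:
    """Solver settings for the constrained unmixing fits."""

    alpha_bounds: tuple[float, float] = (0.0, 1.0)
    residual_change_tol: float = 1e-6
    max_iterations: int = 10_000
    n_starts: int = 8
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.alpha_bounds
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError("alpha bounds must satisfy 0 <= lo < hi <= 1")
        if self.residual_change_tol <= 0:
            raise ValueError("residual change tolerance must be positive")


@dataclass
class UnmixResult:
    """Fit result: correction exponent, amplitudes, fractions and diagnostics."""

    alpha: float
    amplitudes: dict
    fractions: dict
    gaussian_fit: dict
    corrected: Spectrum
    model: Spectrum
    mse: float
    converged: bool
    alpha_identifiable: bool
    method: str = "adaptive"
    nobs: int = 0
    options: FitOptions | None = None

    def redox_ratio(self) -> float:
        from .metrics import redox_ratio

        return redox_ratio(self.fractions)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "alpha": self.alpha,
            "alpha_identifiable": self.alpha_identifiable,
            "amplitudes": dict(self.amplitudes),
            "fractions": dict(self.fractions),
            "gaussian_fit": {k: list(v) for k, v in self.gaussian_fit.items()},
            "mse": self.mse,
            "converged": self.converged,
            "nobs": self.nobs,
        }

    def to_json(self, path) -> None:
        from pathlib import Path

        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    def summary(self) -> str:
        lines = [
            "Reflectance-corrected unmixing fit",
            "=" * 42,
            f"method:              {self.method}",
            f"alpha:               {self.alpha:.4f}"
            + ("" if self.alpha_identifiable else "  (unidentifiable: constant R)"),
            f"mse:                 {self.mse:.4e}",
            f"n wavelengths:       {self.nobs}",
            f"converged:           {self.converged}",
            "-" * 42,
            f"{'component':<16}{'amplitude':>12}{'fraction':>12}",
        ]
        for name in self.amplitudes:
            lines.append(
                f"{name:<16}{self.amplitudes[name]:>12.4g}{self.fractions[name]:>12.4f}"
            )
        if self.gaussian_fit:
            lines.append("-" * 42)
            lines.append(f"{'component':<16}{'mu (nm)':>12}{'sigma (nm)':>12}")
            for name, (mu, sigma) in self.gaussian_fit.items():
                lines.append(f"{name:<16}{mu:>12.2f}{sigma:>12.2f}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Overlay the corrected spectrum, the model sum, and each component."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.corrected.wavelengths, self.corrected.values,
                color="k", lw=1, label="corrected data")
        ax.plot(self.model.wavelengths, self.model.values,
                color="C3", lw=1.5, label="model sum")
        ax.set_xlabel("wavelength (nm)")
        ax.set_ylabel("normalized intensity")
        ax.legend(fontsize=8)
        return ax


class ReflectanceCorrection:
    """Model object pairing one fluorescence spectrum with its reflectance.

    Parameters
    ----------
    fluorescence, reflectance : Spectrum
        Reduced measurement pair.  The fluorescence spectrum is restricted to
        the library fit range and normalized to unit integral there; the
        reflectance is resampled onto the same grid and clamped to
        [R_FLOOR, 1].
    library : BasisLibrary
        Component set (measured bases + constrained Gaussians).
    options : FitOptions, optional

    The corrected data term F_m/R**alpha is *not* re-normalized inside the
    objective; re-normalizing would couple alpha nonlinearly into the data.
    Display normalization of corrected spectra is a separate, presentation-
    level step.
    """

    def __init__(self, fluorescence: Spectrum, reflectance: Spectrum,
                 library: BasisLibrary, options: FitOptions | None = None):
        self.library = library
        self.options = options or FitOptions()
        lo, hi = library.fit_range
        fm = fluorescence.restrict(lo, hi)
        if not np.all(np.isfinite(fm.values)):
            raise ValueError("fluorescence values must be finite")
        self.fm = normalize_by_integral(fm)
        r = resample_to_grid(reflectance, self.fm.wavelengths)
        if np.any(r.values <= 0):
            raise ValueError("reflectance must be positive on the fit range")
        self.r = r.copy(values=np.clip(r.values, R_FLOOR, 1.0))
        self.grid = self.fm.wavelengths
        self._measured_cols = library.design_matrix(self.grid) \
            if not library.gaussian else None

    # -- helpers -----------------------------------------------------------
    @property
    def r_is_constant(self) -> bool:
        rv = self.r.values
        return (rv.max() - rv.min()) <= CONSTANT_R_RTOL * abs(rv.mean())

    def _design(self, gaussian_params: dict | None = None) -> np.ndarray:
        if self._measured_cols is not None and not gaussian_params:
            return self._measured_cols
        return self.library.design_matrix(self.grid, gaussian_params)

    def _inner_solve(self, alpha: float, gaussian_params: dict | None = None):
        """Nonnegative amplitude solve at fixed shape parameters."""
        y = self.fm.values / self.r.values ** alpha
        a = self._design(gaussian_params)
        c, _ = nnls(a, y)
        resid = y - a @ c
        return c, resid, y, a

    def _theta_layout(self):
        """Pack (alpha, mu_i, sigma_i) with bounds; alpha omitted when frozen."""
        lo_a, hi_a = self.options.alpha_bounds
        lows, highs, mids = [lo_a], [hi_a], [0.5 * (lo_a + hi_a)]
        for g in self.library.gaussian:
            lows += [g.mu_bounds[0], g.sigma_bounds[0]]
            highs += [g.mu_bounds[1], g.sigma_bounds[1]]
            mids += [g.mu0, g.sigma0]
        return np.array(lows), np.array(highs), np.array(mids)

    def _unpack_gaussian(self, theta_tail: np.ndarray) -> dict:
        out = {}
        for i, g in enumerate(self.library.gaussian):
            out[g.name] = (float(theta_tail[2 * i]), float(theta_tail[2 * i + 1]))
        return out

    def _result(self, alpha, gaussian_params, method, converged,
                alpha_identifiable=True) -> UnmixResult:
        c, resid, y, a = self._inner_solve(alpha, gaussian_params)
        names = self.library.component_names
        total = c.sum()
        fractions = {n: (float(ci) / total if total > 0 else 0.0)
                     for n, ci in zip(names, c)}
        corrected = Spectrum(self.grid, y, "corrected")
        model = Spectrum(self.grid, a @ c, "corrected")
        return UnmixResult(
            alpha=float(alpha),
            amplitudes={n: float(ci) for n, ci in zip(names, c)},
            fractions=fractions,
            gaussian_fit=dict(gaussian_params or {}),
            corrected=corrected,
            model=model,
            mse=float(np.mean(resid ** 2)),
            converged=bool(converged),
            alpha_identifiable=alpha_identifiable,
            method=method,
            nobs=int(self.grid.size),
            options=self.options,
        )

    # -- fitting -----------------------------------------------------------
    def fit(self, method: str = "adaptive", alpha: float | None = None) -> UnmixResult:
        """Fit the unmixing model.

        method : {"adaptive", "kim", "valdes", "none"}
            "adaptive" optimizes alpha per measurement; "kim" freezes
            alpha = 1; "valdes" freezes alpha at the supplied calibrated
            value; "none" applies no correction (alpha = 0).
        """
        if method == "adaptive":
            return self._fit_adaptive()
        if method == "kim":
            return self._fit_fixed(1.0, "kim")
        if method == "none":
            return self._fit_fixed(0.0, "none")
        if method == "valdes":
            if alpha is None:
                raise ValueError("method='valdes' requires a calibrated alpha")
            return self._fit_fixed(float(alpha), "valdes")
        raise ValueError(f"unknown method {method!r}")

    def _fit_fixed(self, alpha: float, method: str) -> UnmixResult:
        if not np.isfinite(alpha):
            raise ValueError("alpha must be finite")
        if not self.library.gaussian:
            return self._result(alpha, None, method, converged=True)
        # bounded nonlinear least squares over Gaussian shapes only
        lows, highs, mids = self._theta_layout()
        lows, highs, mids = lows[1:], highs[1:], mids[1:]

        def resid_fn(theta):
            gp = self._unpack_gaussian(theta)
            _, resid, _, _ = self._inner_solve(alpha, gp)
            return resid

        sol = least_squares(resid_fn, mids, bounds=(lows, highs),
                            ftol=self.options.residual_change_tol * 1e-3,
                            xtol=1e-12, gtol=1e-12,
                            max_nfev=self.options.max_iterations)
        gp = self._unpack_gaussian(sol.x)
        return self._result(alpha, gp, method, converged=sol.status > 0)

    def _fit_adaptive(self, x0: np.ndarray | None = None) -> UnmixResult:
        opts = self.options
        if self.r_is_constant:
            res = self._fit_fixed(0.0, "adaptive")
            res.alpha_identifiable = False
            return res
        lows, highs, mids = self._theta_layout()

        def resid_fn(theta):
            gp = self._unpack_gaussian(theta[1:]) if theta.size > 1 else None
            _, resid, _, _ = self._inner_solve(theta[0], gp)
            return resid

        rng = np.random.default_rng(opts.seed)
        starts = [np.asarray(x0, dtype=float)] if x0 is not None else [mids]
        n_extra = 0 if x0 is not None else max(opts.n_starts - 1, 0)
        for _ in range(n_extra):
            starts.append(lows + rng.random(lows.size) * (highs - lows))

        best = None
        any_ok = False
        for start in starts:
            try:
                sol = least_squares(resid_fn, start, bounds=(lows, highs),
                                    ftol=opts.residual_change_tol * 1e-3,
                                    xtol=1e-12, gtol=1e-12,
                                    max_nfev=opts.max_iterations)
            except Exception:  # noqa: BLE001 - collect diagnostics across starts
                continue
            any_ok = any_ok or sol.status > 0
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None:
            raise RuntimeError("optimizer failed on all starts")
        theta = best.x
        gp = self._unpack_gaussian(theta[1:]) if theta.size > 1 else None
        alpha = float(theta[0])
        if not self.library.gaussian:
            # polish the 1-D alpha search; the inner solve makes the profile
            # piecewise smooth, so a bounded scalar refinement is cheap and robust
            lo = max(opts.alpha_bounds[0], alpha - 0.05)
            hi = min(opts.alpha_bounds[1], alpha + 0.05)

            def cost(a):
                _, resid, _, _ = self._inner_solve(a)
                return float(resid @ resid)

            pol = minimize_scalar(cost, bounds=(lo, hi), method="bounded",
                                  options={"xatol": 1e-8})
            if pol.fun <= 2 * best.cost:
                alpha = float(pol.x)
        return self._result(alpha, gp, "adaptive", converged=any_ok)


# ---------------------------------------------------------------------------
# functional surface
# ---------------------------------------------------------------------------

def correct_power(fm: Spectrum, r: Spectrum, alpha: float) -> Spectrum:
    """Elementwise F_m(lam) / R(lam)**alpha.

    alpha = 1 is the Kim-style linear correction; alpha = 0 is the identity.
    """
    if not np.array_equal(fm.wavelengths, r.wavelengths):
        raise ValueError("fluorescence and reflectance must share a grid")
    if not np.isfinite(alpha):
        raise ValueError("alpha must be finite")
    if np.any(r.values <= 0):
        raise ValueError("reflectance must be positive")
    vals = fm.values / r.values ** alpha
    return Spectrum(fm.wavelengths, vals, "corrected", dict(fm.meta))


def fit_fixed_alpha(fm: Spectrum, r: Spectrum, alpha: float,
                    library: BasisLibrary,
                    options: FitOptions | None = None) -> UnmixResult:
    """Unmix with the correction exponent frozen (Kim: alpha=1; Valdes: calibrated)."""
    model = ReflectanceCorrection(fm, r, library, options)
    method = "kim" if alpha == 1.0 else ("none" if alpha == 0.0 else "valdes")
    return model._fit_fixed(float(alpha), method)


def fit_adaptive(fm: Spectrum, r: Spectrum, library: BasisLibrary,
                 options: FitOptions | None = None) -> UnmixResult:
    """Jointly fit alpha, amplitudes and Gaussian shapes for one measurement."""
    return ReflectanceCorrection(fm, r, library, options).fit("adaptive")


@dataclass
class ValdesCalibration:
    """Single shared correction exponent per excitation, phantom-calibrated."""

    alpha_by_excitation: dict
    phantom_ids: list = field(default_factory=list)
    total_residual: float = 0.0

    def to_json(self, path) -> None:
        from pathlib import Path

        Path(path).write_text(json.dumps({
            "alpha_by_excitation": self.alpha_by_excitation,
            "phantom_ids": self.phantom_ids,
            "total_residual": self.total_residual,
        }, indent=1))

    @classmethod
    def from_json(cls, path) -> "ValdesCalibration":
        from pathlib import Path

        doc = json.loads(Path(path).read_text())
        return cls(doc["alpha_by_excitation"], doc.get("phantom_ids", []),
                   doc.get("total_residual", 0.0))


def calibrate_valdes_alpha(pairs: list, excitation_nm, library: BasisLibrary,
                           options: FitOptions | None = None,
                           phantom_ids: list | None = None) -> ValdesCalibration:
    """Calibrate one shared alpha over a set of (fluorescence, reflectance) pairs.

    Minimizes the summed unmixing residual with a single alpha for all pairs
    and per-pair amplitudes (and Gaussian shapes where the library has any).
    Separability makes this an outer 1-D bounded search over alpha with
    independent inner solves per pair.
    """
    if not pairs:
        raise ValueError("need at least one (fluorescence, reflectance) pair")
    options = options or FitOptions()
    models = [ReflectanceCorrection(fm, r, library, options) for fm, r in pairs]

    def total_cost(alpha: float) -> float:
        tot = 0.0
        for m in models:
            if m.library.gaussian:
                res = m._fit_fixed(alpha, "valdes")
                tot += res.mse * res.nobs
            else:
                _, resid, _, _ = m._inner_solve(alpha)
                tot += float(resid @ resid)
        return tot

    lo, hi = options.alpha_bounds
    grid = np.linspace(lo, hi, 41)
    costs = [total_cost(a) for a in grid]
    k = int(np.argmin(costs))
    blo = grid[max(k - 1, 0)]
    bhi = grid[min(k + 1, grid.size - 1)]
    sol = minimize_scalar(total_cost, bounds=(blo, bhi), method="bounded",
                          options={"xatol": 1e-6})
    alpha = float(sol.x)
    return ValdesCalibration(
        alpha_by_excitation={str(excitation_nm): alpha},
        phantom_ids=list(phantom_ids or range(len(pairs))),
        total_residual=float(sol.fun),
    )


def alpha_profile_oracle(fm: Spectrum, r: Spectrum, library: BasisLibrary,
                         grid_step: float = 1e-3,
                         options: FitOptions | None = None):
    """Brute-force residual profile over an alpha grid (Gaussian shapes frozen).

    Independent check of the adaptive fit: for each alpha on a uniform grid
    over [0, 1], solve the inner nonnegative least squares and record the
    residual sum of squares.  Returns (alpha_star, alphas, residuals).
    """
    if not (0 < grid_step <= 0.1):
        raise ValueError("grid_step must lie in (0, 0.1]")
    model = ReflectanceCorrection(fm, r, library, options)
    frozen = {g.name: (g.mu0, g.sigma0) for g in library.gaussian} or None
    lo, hi = model.options.alpha_bounds
    alphas = np.arange(lo, hi + grid_step / 2, grid_step)
    costs = np.empty_like(alphas)
    for i, a in enumerate(alphas):
        _, resid, _, _ = model._inner_solve(a, frozen)
        costs[i] = resid @ resid
    k = int(np.argmin(costs))
    return float(alphas[k]), alphas, costs


def multistart_robustness(fm: Spectrum, r: Spectrum, library: BasisLibrary,
                          n_starts: int = 100, seed: int = 0,
                          options: FitOptions | None = None) -> dict:
    """Sensitivity of the adaptive fit to its starting point.

    Runs the fit from ``n_starts`` random feasible initializations and reports
    the spread of (alpha, fractions) among runs whose final absolute residual
    integral is below 5% of the integral of F_m (which is 1 after
    normalization).
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    options = options or FitOptions()
    model = ReflectanceCorrection(fm, r, library, options)
    if model.r_is_constant:
        return {"n_starts": n_starts, "n_converged": 0, "n_accepted": 0,
                "alpha_dispersion": None, "fraction_dispersion": None,
                "alpha_identifiable": False}
    lows, highs, _ = model._theta_layout()
    rng = np.random.default_rng(seed)
    dlam = np.gradient(model.grid)
    alphas, fracs = [], []
    n_conv = 0
    for _ in range(n_starts):
        x0 = lows + rng.random(lows.size) * (highs - lows)
        res = model._fit_adaptive(x0=x0)
        if res.converged:
            n_conv += 1
        resid_integral = float(
            np.sum(np.abs(res.corrected.values - res.model.values) * dlam))
        if resid_integral < 0.05:
            alphas.append(res.alpha)
            fracs.append([res.fractions[n] for n in library.component_names])
    report = {"n_starts": n_starts, "n_converged": n_conv,
              "n_accepted": len(alphas), "alpha_identifiable": True}
    if alphas:
        fr = np.array(fracs)
        report["alpha_dispersion"] = float(np.max(alphas) - np.min(alphas))
        report["fraction_dispersion"] = {
            n: float(fr[:, j].max() - fr[:, j].min())
            for j, n in enumerate(library.component_names)
        }
    else:
        report["alpha_dispersion"] = None
        report["fraction_dispersion"] = None
    return report
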