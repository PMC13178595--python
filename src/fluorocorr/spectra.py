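"""Spectral data model and reduction of raw fiber-probe acquisitions.

A measurement session interleaves shutter-open ("signal") and shutter-closed
("background") frames for diffuse reflectance (broadband lamp) and for
fluorescence at each laser line.  This module reduces such raw frame sets into
a single power-normalized fluorescence spectrum and a white-standard
calibrated reflectance spectrum, the two inputs the correction models consume.

Spectra are stored as plain (wavelength_nm, value) pairs; files are two-column
delimited text with ``#``-prefixed ``key: value`` header lines.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

#: lower clamp applied to calibrated reflectance; the correction divides by
#: R**alpha, so R must stay bounded away from zero.
R_FLOOR = 1e-4

SPECTRUM_KINDS = ("raw", "fluorescence", "reflectance", "corrected", "basis")


def validate_grid(wavelengths: np.ndarray) -> np.ndarray:
    """Validate a wavelength grid: finite, positive, strictly increasing, >= 2 points."""
    grid = np.asarray(wavelengths, dtype=float)
    if grid.ndim != 1 or grid.size < 2:
        raise ValueError("wavelength grid must be 1-D with at least 2 points")
    if not np.all(np.isfinite(grid)) or np.any(grid <= 0):
        raise ValueError("wavelengths must be finite and positive (nm)")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("wavelengths must be strictly increasing")
    return grid


@dataclass
class Spectrum:
    """A spectrum sampled on a wavelength grid.

    Parameters
    ----------
    wavelengths : array, nm, strictly increasing
    values : array, same length; counts, counts/s/mW or dimensionless
    kind : one of {raw, fluorescence, reflectance, corrected, basis}
    meta : free-form metadata (excitation_nm, power_mW, ...)
    """

    wavelengths: np.ndarray
    values: np.ndarray
    kind: str = "raw"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.wavelengths = validate_grid(self.wavelengths)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.wavelengths.shape:
            raise ValueError(
                f"values length {self.values.size} != grid length {self.wavelengths.size}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("spectrum values must all be finite")
        if self.kind not in SPECTRUM_KINDS:
            raise ValueError(f"unknown spectrum kind {self.kind!r}")

    # -- convenience -------------------------------------------------------
    def copy(self, **changes) -> "Spectrum":
        out = replace(self, **changes)
        out.meta = dict(changes.get("meta", self.meta))
        return out

    def restrict(self, lo: float, hi: float) -> "Spectrum":
        """Slice to grid points with lo <= wavelength <= hi."""
        mask = (self.wavelengths >= lo) & (self.wavelengths <= hi)
        if mask.sum() < 2:
            raise ValueError(f"fewer than 2 grid points inside [{lo}, {hi}] nm")
        return Spectrum(self.wavelengths[mask], self.values[mask], self.kind, dict(self.meta))

    def integral(self, rng: tuple[float, float] | None = None) -> float:
        """Trapezoidal integral, optionally over a wavelength range."""
        if rng is None:
            return float(np.trapezoid(self.values, self.wavelengths))
        lo, hi = rng
        s = self.restrict(lo, hi)
        return float(np.trapezoid(s.values, s.wavelengths))

    def value_at(self, wavelength: float, tol: float = 1.0) -> float:
        """Value at the nearest grid point within ``tol`` nm."""
        idx = int(np.argmin(np.abs(self.wavelengths - wavelength)))
        if abs(self.wavelengths[idx] - wavelength) > tol:
            raise ValueError(
                f"no grid point within {tol} nm of {wavelength} nm "
                f"(nearest: {self.wavelengths[idx]} nm)"
            )
        return float(self.values[idx])


@dataclass
class AcquisitionProtocol:
    """Timing of the interleaved acquisition sequence.

    ``n_reflectance`` lamp frames (each paired with a background) followed by
    ``n_fluor_repeats`` repeats of the four-frame fluorescence block
    (background, 375 nm, background, 405 nm), all at integration time
    ``integration_time_s``.
    """

    integration_time_s: float = 0.2
    n_reflectance: int = 5
    n_fluor_repeats: int = 5
    excitation_powers_mW: dict = field(default_factory=lambda: {"375": 1.0, "405": 1.0})

    def __post_init__(self):
        if self.integration_time_s <= 0:
            raise ValueError("integration time must be positive")
        if self.n_reflectance < 1 or self.n_fluor_repeats < 1:
            raise ValueError("frame counts must be >= 1")

    @property
    def total_duration_s(self) -> float:
        return (2 * self.n_reflectance + 4 * self.n_fluor_repeats) * self.integration_time_s


@dataclass
class RawAcquisitionSet:
    """Interleaved signal/background frames for one excitation tag."""

    excitation_tag: str  # "375", "405" or "white"
    signal_frames: list
    background_frames: list

    def __post_init__(self):
        if len(self.signal_frames) != len(self.background_frames):
            raise ValueError("each signal frame needs a paired background frame")
        if not self.signal_frames:
            raise ValueError("acquisition set has no frames")
        for s, b in zip(self.signal_frames, self.background_frames):
            if not np.array_equal(s.wavelengths, b.wavelengths):
                raise ValueError("signal and background frames must share a grid")


# ---------------------------------------------------------------------------
# reduction operations
# ---------------------------------------------------------------------------

def subtract_background(signal: Spectrum, background: Spectrum) -> Spectrum:
    """Elementwise signal - background; grids must match exactly.

    Negative results are allowed at this stage (noise floor).
    """
    if not np.array_equal(signal.wavelengths, background.wavelengths):
        raise ValueError(
            "grid mismatch: signal grid "
            f"[{signal.wavelengths[0]}..{signal.wavelengths[-1]}] x{signal.wavelengths.size} "
            f"vs background grid "
            f"[{background.wavelengths[0]}..{background.wavelengths[-1]}] x{background.wavelengths.size}"
        )
    return Spectrum(signal.wavelengths, signal.values - background.values,
                    signal.kind, dict(signal.meta))


def average_repeats(frames: list, anomaly_z: float = 5.0):
    """Average repeated frames after flagging anomalous ones.

    A frame is flagged when its integrated intensity deviates from the median
    integrated intensity by more than ``anomaly_z`` robust standard deviations
    (median/MAD screening; an automatable stand-in for visual QC of motion
    artifacts).

    Returns
    -------
    (mean_spectrum, flags) where flags is a boolean array (True = excluded).
    """
    if not frames:
        raise ValueError("need at least one frame")
    grid = frames[0].wavelengths
    for f in frames[1:]:
        if not np.array_equal(f.wavelengths, grid):
            raise ValueError("frames must share a common grid")
    integrals = np.array([f.integral() for f in frames])
    med = np.median(integrals)
    mad = np.median(np.abs(integrals - med))
    scale = 1.4826 * mad
    if scale > 0:
        z = np.abs(integrals - med) / scale
    else:
        # all-but-outlier identical integrals: any deviation is anomalous
        z = np.where(integrals == med, 0.0, np.inf)
    flags = z > anomaly_z
    if flags.all():
        raise ValueError("no valid frames: all repeats flagged as anomalous")
    stack = np.stack([f.values for f, bad in zip(frames, flags) if not bad])
    mean = Spectrum(grid, stack.mean(axis=0), frames[0].kind, dict(frames[0].meta))
    return mean, flags


def normalize_by_power(spectrum: Spectrum, power_mW: float) -> Spectrum:
    """Divide by laser power; fluorescence becomes counts/s/mW-comparable."""
    if power_mW <= 0:
        raise ValueError(f"power must be positive, got {power_mW}")
    return spectrum.copy(values=spectrum.values / power_mW)


def calibrate_reflectance(sample_mean: Spectrum, standard_mean: Spectrum,
                          standard_reflectivity: float = 0.99) -> Spectrum:
    """Ratio a background-subtracted sample to the white-standard acquisition.

    R(lam) = standard_reflectivity * sample(lam) / standard(lam), clamped to
    [R_FLOOR, 1]; clamping is logged, never silent.
    """
    if not np.array_equal(sample_mean.wavelengths, standard_mean.wavelengths):
        raise ValueError("sample and standard must share a grid")
    bad = standard_mean.values <= 0
    if bad.any():
        raise ValueError(
            "white standard nonpositive at wavelengths: "
            f"{sample_mean.wavelengths[bad][:10].tolist()}"
        )
    r = standard_reflectivity * sample_mean.values / standard_mean.values
    n_hi = int((r > 1.0).sum())
    n_lo = int((r < R_FLOOR).sum())
    if n_hi or n_lo:
        logger.warning(
            "calibrated reflectance clamped at %d points above 1 and %d below %g",
            n_hi, n_lo, R_FLOOR,
        )
    r = np.clip(r, R_FLOOR, 1.0)
    return Spectrum(sample_mean.wavelengths, r, "reflectance", dict(sample_mean.meta))


def normalize_by_integral(spectrum: Spectrum,
                          rng: tuple[float, float] | None = None) -> Spectrum:
    """Scale so the trapezoidal integral over ``rng`` (default: full grid) is 1."""
    area = spectrum.integral(rng)
    if area <= 0:
        raise ValueError(f"integral over {rng or 'full range'} is nonpositive ({area})")
    return spectrum.copy(values=spectrum.values / area)


def resample_to_grid(spectrum: Spectrum, target: np.ndarray) -> Spectrum:
    """Linear interpolation onto ``target``; no extrapolation allowed."""
    target = validate_grid(target)
    if target[0] < spectrum.wavelengths[0] or target[-1] > spectrum.wavelengths[-1]:
        raise ValueError(
            f"target grid [{target[0]}, {target[-1]}] extends beyond source span "
            f"[{spectrum.wavelengths[0]}, {spectrum.wavelengths[-1]}]"
        )
    vals = np.interp(target, spectrum.wavelengths, spectrum.values)
    return Spectrum(target, vals, spectrum.kind, dict(spectrum.meta))


def coefficient_of_variation(frames: list, at: float = 510.0, tol: float = 1.0) -> float:
    """Sample SD / mean of the frame values at the grid point nearest ``at`` nm."""
    if len(frames) < 2:
        raise ValueError("need at least 2 frames for a coefficient of variation")
    vals = np.array([f.value_at(at, tol) for f in frames])
    mean = vals.mean()
    if mean <= 0:
        raise ValueError(f"mean at {at} nm is nonpositive ({mean})")
    return float(vals.std(ddof=1) / mean)


# ---------------------------------------------------------------------------
# full reduction pipeline
# ---------------------------------------------------------------------------

def reduce_fluorescence(raw: RawAcquisitionSet, power_mW: float,
                        integration_time_s: float = 1.0,
                        anomaly_z: float = 5.0) -> Spectrum:
    """Background-subtract each repeat, average, and normalize by laser power.

    Also returns counts per second via the integration time.
    """
    diffs = [subtract_background(s, b)
             for s, b in zip(raw.signal_frames, raw.background_frames)]
    mean, _ = average_repeats(diffs, anomaly_z)
    mean = mean.copy(values=mean.values / integration_time_s)
    out = normalize_by_power(mean, power_mW)
    return out.copy(kind="fluorescence")


def reduce_reflectance(raw: RawAcquisitionSet, standard: RawAcquisitionSet,
                       standard_reflectivity: float = 0.99,
                       anomaly_z: float = 5.0) -> Spectrum:
    """Background-subtract and average sample and standard sets, then ratio."""
    sample_diffs = [subtract_background(s, b)
                    for s, b in zip(raw.signal_frames, raw.background_frames)]
    std_diffs = [subtract_background(s, b)
                 for s, b in zip(standard.signal_frames, standard.background_frames)]
    sample_mean, _ = average_repeats(sample_diffs, anomaly_z)
    std_mean, _ = average_repeats(std_diffs, anomaly_z)
    return calibrate_reflectance(sample_mean, std_mean, standard_reflectivity)


# ---------------------------------------------------------------------------
# file I/O: two-column text spectra and JSON bundle manifests
# ---------------------------------------------------------------------------

def write_spectrum(spectrum: Spectrum, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# kind: {spectrum.kind}\n")
        for k, v in spectrum.meta.items():
            fh.write(f"# {k}: {v}\n")
        for lam, val in zip(spectrum.wavelengths, spectrum.values):
            fh.write(f"{lam:.6g}\t{val:.10g}\n")


def read_spectrum(path) -> Spectrum:
    path = Path(path)
    meta: dict = {}
    lams, vals = [], []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    k, _, v = body.partition(":")
                    meta[k.strip()] = v.strip()
                continue
            parts = line.replace(",", "\t").split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected two columns, got {line!r}")
            try:
                lams.append(float(parts[0]))
                vals.append(float(parts[1]))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: unparseable numbers in {line!r}") from exc
    kind = meta.pop("kind", "raw")
    return Spectrum(np.asarray(lams), np.asarray(vals), kind, meta)


def write_bundle(bundle: dict, directory) -> Path:
    """Write a dict of tag -> RawAcquisitionSet as text frames plus a manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {}
    for tag, raw in bundle.items():
        entries = []
        for i, (s, b) in enumerate(zip(raw.signal_frames, raw.background_frames)):
            spath = directory / f"{tag}_signal_{i}.tsv"
            bpath = directory / f"{tag}_background_{i}.tsv"
            write_spectrum(s, spath)
            write_spectrum(b, bpath)
            entries.append({"signal": spath.name, "background": bpath.name})
        manifest[tag] = entries
    mpath = directory / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1))
    return mpath


def read_bundle(directory) -> dict:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    out = {}
    for tag, entries in manifest.items():
        sig = [read_spectrum(directory / e["signal"]) for e in entries]
        bg = [read_spectrum(directory / e["background"]) for e in entries]
        out[tag] = RawAcquisitionSet(tag, sig, bg)
    return out
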