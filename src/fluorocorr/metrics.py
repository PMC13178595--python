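"""Detection/quantification metrics and timecourse trend summaries.

Detection over a phantom suite is scored per (phantom, fluorophore) pair:
a fluorophore is "detected" when its recovered relative fraction exceeds a
small threshold (default 0.01 — fractions of 1-3% are treated as meaningful
contributions while numerically-zero amplitudes are not).  Sensitivity and
specificity follow the usual TP/(TP+FN) and TN/(TN+FP) definitions; the mean
absolute error over recovered vs true fractions is the quantification metric.

For perfusion timecourses, per-phase ordinary least-squares lines summarize
the drift of each fluorophore fraction and of the optical redox ratio
c_FAD / (c_FAD + c_NADH).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_DETECTION_THRESHOLD = 0.01


@dataclass(frozen=True)
class DetectionOutcome:
    """Presence call for one (phantom, fluorophore) pair."""

    phantom_id: str
    fluorophore: str
    truth_present: bool
    detected: bool

    @property
    def outcome_class(self) -> str:
        if self.truth_present:
            return "TP" if self.detected else "FN"
        return "FP" if self.detected else "TN"


def detect(fractions: dict, threshold: float = DEFAULT_DETECTION_THRESHOLD) -> dict:
    """Presence flags: detected iff fraction > threshold.

    Thresholds must lie in (0, 0.5): above 0.5 at most one component could
    ever be called present, which defeats multi-fluorophore detection.
    """
    if not (0 < threshold < 0.5):
        raise ValueError(f"threshold must lie in (0, 0.5), got {threshold}")
    return {name: frac > threshold for name, frac in fractions.items()}


def confusion_counts(outcomes: list) -> dict:
    counts = {"TP": 0, "FP": 0, "TN": 0, "FN": 0}
    for o in outcomes:
        counts[o.outcome_class] += 1
    return counts


def sensitivity_specificity(counts: dict):
    """(sensitivity %, specificity %); None when a denominator is zero."""
    pos = counts["TP"] + counts["FN"]
    neg = counts["TN"] + counts["FP"]
    sens = 100.0 * counts["TP"] / pos if pos > 0 else None
    spec = 100.0 * counts["TN"] / neg if neg > 0 else None
    return sens, spec


def mean_absolute_error(measured: np.ndarray, truth: np.ndarray) -> float:
    measured = np.asarray(measured, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if measured.shape != truth.shape:
        raise ValueError(f"shape mismatch: {measured.shape} vs {truth.shape}")
    return float(np.mean(np.abs(measured - truth)))


def redox_ratio(fractions: dict) -> float | None:
    """Optical redox ratio c_FAD / (c_FAD + c_NADH); None when both are zero."""
    fad = fractions.get("FAD", 0.0)
    nadh = fractions.get("NADH", 0.0)
    if fad + nadh <= 0:
        return None
    return float(fad / (fad + nadh))


@dataclass(frozen=True)
class MetricsReport:
    """Suite-level detection and quantification summary."""

    sensitivity: float | None
    specificity: float | None
    mae: float
    counts: dict
    n_pairs: int

    def formatted(self) -> str:
        sens = "n/a" if self.sensitivity is None else f"{self.sensitivity:.1f}"
        spec = "n/a" if self.specificity is None else f"{self.specificity:.1f}"
        return f"sensitivity {sens}%  specificity {spec}%  MAE {self.mae:.3f}"


def score_suite(records: list, threshold: float = DEFAULT_DETECTION_THRESHOLD) -> MetricsReport:
    """Score a list of (phantom_id, measured_fractions, truth_fractions) records.

    Truth presence is truth fraction > 0; detection uses the threshold rule.
    MAE runs over every (phantom, fluorophore) pair.
    """
    outcomes = []
    measured_all, truth_all = [], []
    for phantom_id, measured, truth in records:
        flags = detect(measured, threshold)
        for name in truth:
            outcomes.append(DetectionOutcome(
                str(phantom_id), name,
                truth_present=truth[name] > 0,
                detected=bool(flags.get(name, False)),
            ))
            measured_all.append(measured.get(name, 0.0))
            truth_all.append(truth[name])
    counts = confusion_counts(outcomes)
    sens, spec = sensitivity_specificity(counts)
    mae = mean_absolute_error(np.array(measured_all), np.array(truth_all))
    return MetricsReport(sens, spec, mae, counts, len(outcomes))


# ---------------------------------------------------------------------------
# timecourse trends
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhaseTrend:
    """OLS line for one tracked quantity within one protocol phase."""

    phase: str
    quantity: str
    slope: float | None  # per minute; None for intercept-only records
    intercept: float
    n_points: int


def phase_trends(timecourse: list, phases: list) -> list:
    """Per-phase linear trends of fluorophore fractions and the redox ratio.

    Parameters
    ----------
    timecourse : list of (timestamp_min, fractions-dict or UnmixResult)
    phases : list of (name, start_min, end_min); windows are half-open
        [start, end) and must not overlap.
    """
    ordered = sorted(phases, key=lambda p: p[1])
    for (_, s1, e1), (_, s2, _) in zip(ordered, ordered[1:]):
        if s2 < e1:
            raise ValueError("phase windows overlap")
    rows = []
    for t, entry in timecourse:
        fr = entry.fractions if hasattr(entry, "fractions") else dict(entry)
        row = {"t": float(t), **fr}
        rr = redox_ratio(fr)
        if rr is not None:
            row["redox_ratio"] = rr
        rows.append(row)
    df = pd.DataFrame(rows)
    quantities = [c for c in df.columns if c != "t"]
    trends = []
    for name, start, end in phases:
        sub = df[(df["t"] >= start) & (df["t"] < end)]
        for q in quantities:
            vals = sub[q].dropna()
            tt = sub.loc[vals.index, "t"]
            if len(vals) >= 2 and tt.nunique() > 1:
                slope, intercept = np.polyfit(tt.values, vals.values, 1)
                trends.append(PhaseTrend(name, q, float(slope), float(intercept),
                                         len(vals)))
            elif len(vals) >= 1:
                trends.append(PhaseTrend(name, q, None, float(vals.mean()),
                                         len(vals)))
    return trends


def trends_table(trends: list) -> pd.DataFrame:
    return pd.DataFrame(
        [{"phase": t.phase, "quantity": t.quantity, "slope_per_min": t.slope,
          "intercept": t.intercept, "n_points": t.n_points} for t in trends]
    )


# ---------------------------------------------------------------------------
# suite-level method comparison
# ---------------------------------------------------------------------------

def evaluate_suite(records: list, library, methods=("new", "valdes", "kim"),
                   threshold: float = DEFAULT_DETECTION_THRESHOLD,
                   options=None) -> pd.DataFrame:
    """Score each correction method on a simulated phantom suite.

    ``records`` are SuiteRecord objects (or dicts from a suite directory).
    The Valdes-style fixed exponent is calibrated on the suite itself, one
    value per excitation tag, exactly as it would be in a phantom study.
    Returns one row per method x excitation with sensitivity, specificity and
    MAE at full precision.
    """
    from .models import ReflectanceCorrection, calibrate_valdes_alpha

    def _get(rec, key):
        return rec[key] if isinstance(rec, dict) else getattr(rec, key)

    def _tag(rec):
        return rec["excitation"] if isinstance(rec, dict) else rec.excitation_tag

    tags = sorted({_tag(r) for r in records})
    valdes_alpha = {}
    if "valdes" in methods:
        for tag in tags:
            pairs = [(_get(r, "fluorescence"), _get(r, "reflectance"))
                     for r in records if _tag(r) == tag]
            cal = calibrate_valdes_alpha(pairs, tag, library, options)
            valdes_alpha[tag] = cal.alpha_by_excitation[str(tag)]

    method_map = {"new": ("adaptive", None), "kim": ("kim", None),
                  "none": ("none", None)}
    rows = []
    for tag in tags:
        tag_records = [r for r in records if _tag(r) == tag]
        fits = {}
        for r in tag_records:
            model = ReflectanceCorrection(_get(r, "fluorescence"),
                                          _get(r, "reflectance"), library, options)
            fits[id(r)] = model
        for method in methods:
            scored = []
            for r in tag_records:
                if method == "valdes":
                    res = fits[id(r)].fit("valdes", alpha=valdes_alpha[tag])
                else:
                    fit_method, alpha = method_map[method]
                    res = fits[id(r)].fit(fit_method, alpha=alpha)
                pid = _get(r, "spec").id if not isinstance(r, dict) else r["phantom"]
                scored.append((pid, res.fractions, _get(r, "truth_fractions")))
            report = score_suite(scored, threshold)
            rows.append({
                "method": method, "excitation": tag,
                "sensitivity": report.sensitivity,
                "specificity": report.specificity,
                "mae": report.mae, "n_pairs": report.n_pairs,
                **({"alpha": valdes_alpha[tag]} if method == "valdes" else {}),
            })
    return pd.DataFrame(rows)


def format_report(df: pd.DataFrame) -> str:
    """One-decimal presentation view of an evaluate_suite table."""
    out = df.copy()
    for col in ("sensitivity", "specificity"):
        out[col] = out[col].map(lambda v: "n/a" if v is None else f"{v:.1f}")
    out["mae"] = out["mae"].map(lambda v: f"{v:.3f}")
    cols = ["method", "excitation", "sensitivity", "specificity", "mae"]
    return out[cols].to_string(index=False)
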