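"""Differential scanning fluorimetry (thermofluor) melt-curve analysis.

A DSF melt curve follows dye fluorescence while the sample is heated; the
unfolding transition is the sigmoid

    F(T) = F_min + (F_max - F_min) / (1 + exp((Tm - T) / a))

(the Boltzmann equation in the DSF sense), whose midpoint Tm is the
melting temperature. Thermal shifts ΔTm = Tm(condition) − Tm(reference)
classify screen wells: shifts at or above a configurable effect threshold
are stabilizers, at or below its negative destabilizers.

Real SYPRO-Orange curves decay after the unfolding peak (dye release), so
fitting is restricted to the window from the scan start to the
temperature of maximum (smoothed) fluorescence; the window used is
recorded on every fit. Unconverged or degenerate fits are reported with
``converged=False``, never silently dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.special import expit

from .errors import FitNotConvergedError, InsufficientDataError

__all__ = [
    "MeltCurve",
    "BoltzmannFit",
    "ScreenResult",
    "boltzmann",
    "fit_melt_curve",
    "delta_tm",
    "classify_screen",
    "fit_plate",
    "read_plate_csv",
    "melt_curves_from_plate",
    "DEFAULT_EFFECT_THRESHOLD_C",
]

#: |ΔTm| (°C) at/above which a ligand counts as a hit ("best hit" tier);
#: a 1 °C tier is conventional for "any effect" screening
DEFAULT_EFFECT_THRESHOLD_C = 2.0


def boltzmann(
    T: float | np.ndarray,
    F_min: float,
    F_max: float,
    Tm: float,
    a: float,
) -> float | np.ndarray:
    """Four-parameter Boltzmann sigmoid.

    ``a`` (°C) sets the transition width; at T = Tm the value is exactly
    the baseline midpoint (F_min + F_max) / 2. ``a = 0`` is a domain error.
    """
    if a == 0:
        raise ValueError("slope parameter a must be nonzero")
    T = np.asarray(T, dtype=float)
    out = F_min + (F_max - F_min) * expit((T - Tm) / a)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class MeltCurve:
    """One well's temperature–fluorescence series."""

    well_id: str
    condition: str
    temperatures: np.ndarray  # °C, strictly increasing
    fluorescence: np.ndarray  # AU

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures, dtype=float)
        f = np.asarray(self.fluorescence, dtype=float)
        if t.shape != f.shape or t.ndim != 1:
            raise ValueError(f"{self.well_id}: temperature/fluorescence shape mismatch")
        if len(t) < 10:
            raise ValueError(f"{self.well_id}: need >= 10 points, got {len(t)}")
        if not np.all(np.diff(t) > 0):
            raise ValueError(f"{self.well_id}: temperatures must be strictly increasing")
        object.__setattr__(self, "temperatures", t)
        object.__setattr__(self, "fluorescence", f)


@dataclass(frozen=True)
class BoltzmannFit:
    """Fitted sigmoid parameters for one melt curve."""

    Tm: float
    slope_a: float
    F_min: float
    F_max: float
    rss: float
    converged: bool
    fit_window: tuple[float, float]
    message: str = ""


@dataclass(frozen=True)
class ScreenResult:
    condition: str
    Tm: float
    delta_Tm: float
    classification: str  # stabilizer | destabilizer | no_effect | fit_failed


def _smooth(y: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return y
    kernel = np.ones(window) / window
    pad = window // 2
    ypad = np.pad(y, pad, mode="edge")
    return np.convolve(ypad, kernel, mode="valid")[: len(y)]


def fit_melt_curve(
    curve: MeltCurve,
    smooth_window: int = 5,
    max_nfev: int = 500,
) -> BoltzmannFit:
    """Nonlinear least-squares Boltzmann fit over the pre-peak window.

    The fit window runs from the scan start to the temperature of maximum
    smoothed fluorescence (post-peak dye-release decay is excluded).
    Starting values are deterministic: Tm0 at the maximum first difference
    of the smoothed signal, baselines at the window extrema, a0 = 2 °C.
    Convergence tolerance is 1e-10 on the relative cost change within
    ``max_nfev`` function evaluations; a degenerate outcome (inverted or
    zero amplitude, Tm outside the window, non-positive slope) is returned
    with ``converged=False``.
    """
    T = curve.temperatures
    F = curve.fluorescence
    smoothed = _smooth(F, smooth_window)
    if smoothed.max() - smoothed.min() <= 0:
        return BoltzmannFit(
            Tm=math.nan, slope_a=math.nan, F_min=float(F.min()),
            F_max=float(F.max()), rss=math.nan, converged=False,
            fit_window=(float(T[0]), float(T[-1])),
            message="no transition: flat curve",
        )
    peak = int(np.argmax(smoothed))
    stop = peak + 1
    window = (float(T[0]), float(T[stop - 1]))
    if stop < 4:
        raise InsufficientDataError(
            f"{curve.well_id}: only {stop} points before the fluorescence "
            "maximum; a 4-parameter fit needs at least 4"
        )
    Tw, Fw = T[:stop], F[:stop]
    sw = smoothed[:stop]
    amplitude = float(sw.max() - sw.min())
    if amplitude <= 0:
        return BoltzmannFit(
            Tm=math.nan, slope_a=math.nan, F_min=float(Fw.min()),
            F_max=float(Fw.max()), rss=math.nan, converged=False,
            fit_window=window, message="no transition: flat curve",
        )
    diffs = np.diff(sw)
    tm0 = float(Tw[int(np.argmax(diffs))]) if len(diffs) else float(Tw[0])
    p0 = [float(Fw.min()), float(Fw.max()), tm0, 2.0]
    try:
        popt, _ = curve_fit(
            boltzmann, Tw, Fw, p0=p0,
            ftol=1e-10, xtol=1e-10, gtol=1e-10, maxfev=max_nfev * 5,
        )
    except (RuntimeError, ValueError) as exc:
        return BoltzmannFit(
            Tm=math.nan, slope_a=math.nan, F_min=math.nan, F_max=math.nan,
            rss=math.nan, converged=False, fit_window=window,
            message=f"optimizer failure: {exc}",
        )
    f_min, f_max, tm, a = (float(v) for v in popt)
    resid = Fw - boltzmann(Tw, *popt)
    rss = float(np.sum(resid**2))
    ok = (f_min < f_max) and (a > 0) and (window[0] <= tm <= window[1])
    return BoltzmannFit(
        Tm=tm, slope_a=a, F_min=f_min, F_max=f_max, rss=rss,
        converged=ok, fit_window=window,
        message="" if ok else "degenerate fit (amplitude, slope or Tm out of range)",
    )


def delta_tm(fit: BoltzmannFit, reference_fit: BoltzmannFit) -> float:
    """Thermal shift Tm(condition) − Tm(reference), °C. Both fits must have
    converged; otherwise the failure propagates as an error."""
    if not fit.converged or not reference_fit.converged:
        raise FitNotConvergedError("delta_tm requires two converged fits")
    return fit.Tm - reference_fit.Tm


def classify_screen(
    results: Sequence[tuple[str, float | None]],
    effect_threshold_C: float = DEFAULT_EFFECT_THRESHOLD_C,
    tm_by_condition: dict[str, float] | None = None,
) -> list[ScreenResult]:
    """Classify (condition, ΔTm) pairs against an effect threshold.

    ΔTm >= +threshold → stabilizer; <= −threshold → destabilizer;
    otherwise no_effect. A missing/NaN shift marks a failed fit.
    """
    if effect_threshold_C <= 0:
        raise ValueError("effect_threshold_C must be positive")
    out = []
    for condition, delta in results:
        tm = (tm_by_condition or {}).get(condition, math.nan)
        if delta is None or (isinstance(delta, float) and math.isnan(delta)):
            cls = "fit_failed"
            delta = math.nan
        elif delta >= effect_threshold_C:
            cls = "stabilizer"
        elif delta <= -effect_threshold_C:
            cls = "destabilizer"
        else:
            cls = "no_effect"
        out.append(ScreenResult(condition=condition, Tm=tm, delta_Tm=delta,
                                classification=cls))
    return out


# ---------------------------------------------------------------------------
# Plate-level pipeline
# ---------------------------------------------------------------------------

def read_plate_csv(path: str | Path) -> pd.DataFrame:
    """Long-format plate CSV: well, condition, temperature_C, fluorescence_AU."""
    df = pd.read_csv(path)
    required = {"well", "condition", "temperature_C", "fluorescence_AU"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: plate CSV missing columns {sorted(missing)}")
    return df


def melt_curves_from_plate(plate: pd.DataFrame) -> list[MeltCurve]:
    curves = []
    for (well, condition), grp in plate.groupby(["well", "condition"], sort=True):
        grp = grp.sort_values("temperature_C")
        curves.append(
            MeltCurve(
                well_id=str(well), condition=str(condition),
                temperatures=grp["temperature_C"].to_numpy(dtype=float),
                fluorescence=grp["fluorescence_AU"].to_numpy(dtype=float),
            )
        )
    return curves


def fit_plate(
    plate: pd.DataFrame,
    reference: str,
    effect_threshold_C: float = DEFAULT_EFFECT_THRESHOLD_C,
) -> pd.DataFrame:
    """Fit every well, average replicates per condition, classify vs reference.

    Replicate wells of one condition are fitted independently; the
    condition's Tm is the mean over converged replicate fits with its
    standard error. Returns one row per condition: n_replicates,
    n_converged, Tm, Tm_se, delta_Tm, classification.
    """
    curves = melt_curves_from_plate(plate)
    if not any(c.condition == reference for c in curves):
        raise ValueError(f"reference condition {reference!r} not on plate")
    per_condition: dict[str, list[BoltzmannFit]] = {}
    for c in curves:
        per_condition.setdefault(c.condition, []).append(fit_melt_curve(c))
    stats: dict[str, tuple[float, float, int, int]] = {}
    for cond, fits in per_condition.items():
        tms = np.array([f.Tm for f in fits if f.converged])
        n_conv = len(tms)
        if n_conv == 0:
            stats[cond] = (math.nan, math.nan, len(fits), 0)
        else:
            se = float(tms.std(ddof=1) / math.sqrt(n_conv)) if n_conv > 1 else 0.0
            stats[cond] = (float(tms.mean()), se, len(fits), n_conv)
    ref_tm = stats[reference][0]
    if math.isnan(ref_tm):
        raise FitNotConvergedError(f"no converged fit for reference {reference!r}")
    rows = []
    deltas = []
    for cond in sorted(stats):
        tm, se, n_rep, n_conv = stats[cond]
        delta = tm - ref_tm if not math.isnan(tm) else math.nan
        deltas.append((cond, delta))
        rows.append({"condition": cond, "n_replicates": n_rep,
                     "n_converged": n_conv, "Tm": tm, "Tm_se": se,
                     "delta_Tm": delta})
    classified = classify_screen(
        deltas, effect_threshold_C,
        tm_by_condition={c: s[0] for c, s in stats.items()},
    )
    cls_by_cond = {r.condition: r.classification for r in classified}
    df = pd.DataFrame(rows)
    df["classification"] = df["condition"].map(cls_by_cond)
    df.loc[df["condition"] == reference, "classification"] = "reference"
    return df
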