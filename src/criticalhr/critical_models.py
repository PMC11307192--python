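"""Two-parameter linear critical-intensity models.

Critical speed (CS) is the slope of the ordinary least-squares line of
distance on time across maximal efforts; its intercept D′ is the finite
distance reserve usable above CS.  The heartbeat analogue regresses total
heartbeats HB on time in minutes: the slope is the critical heart rate
(CHR, b·min⁻¹) and the intercept HB′ a finite heartbeat reserve.  Time is
the independent variable in both fits.

An alternative parameterization, speed = D′·(1/t) + CS, is provided as a
cross-check; it is algebraically equivalent on noiseless data but weights
noise differently, so on real data the two estimates generally differ and
both are reported rather than reconciled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .errors import ConfigError, FitError
from .effort_metrics import summarize_effort
from .hr_io import EffortTrial

__all__ = [
    "CriticalFit",
    "IntensityPrescription",
    "fit_critical_speed",
    "fit_critical_hr",
    "fit_inverse_time_form",
    "fit_trials",
    "predict_time",
    "prescribe_intensity",
    "relative_intensity",
    "predicted_hrmax",
    "HRMAX_FORMULAS",
]

#: Age-predicted maximal HR formulas, by their conventional names.
HRMAX_FORMULAS = {
    "fox": lambda age: 220.0 - age,            # Fox et al. classic
    "tanaka": lambda age: 208.0 - 0.7 * age,   # Tanaka et al. (default)
    "gellish": lambda age: 207.0 - 0.7 * age,  # Gellish et al.
}


@dataclass(frozen=True)
class CriticalFit:
    """A fitted two-parameter linear model.

    For ``variant='speed'`` the slope is CS in m·s⁻¹ and the intercept D′ in
    m; for ``variant='hr'`` the slope is CHR in b·min⁻¹ and the intercept
    HB′ in beats.  ``parameterization`` records whether the fit came from the
    direct linear form or the inverse-time form.
    """

    variant: str                      # 'speed' | 'hr'
    slope: float
    intercept: float
    r_squared: float
    n_points: int
    residuals: tuple[float, ...]
    se_slope: float
    parameterization: str = "linear"  # 'linear' | 'inverse_time'

    @property
    def slope_m_per_min(self) -> float:
        """CS expressed in m·min⁻¹ (speed variant only)."""
        if self.variant != "speed":
            raise TypeError("m·min⁻¹ conversion applies to the speed variant")
        return self.slope * 60.0


@dataclass(frozen=True)
class IntensityPrescription:
    chr_bpm: float
    target_hr_bpm: float
    zone: str          # 'below_chr' | 'at_chr' | 'above_chr'
    guidance: str


def _check_points(x: np.ndarray, y: np.ndarray, min_points: int = 2) -> None:
    if x.size != y.size:
        raise FitError("mismatched coordinate lengths")
    if x.size < min_points:
        raise FitError(f"need at least {min_points} efforts, got {x.size}")
    if np.unique(x).size < 2:
        raise FitError("singular design: all effort times identical")
    if x.size == 2:
        warnings.warn("only 2 efforts supplied; the protocol recommends 3 distances")


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """Slope, intercept, R², SE(slope) of y ~ x with intercept."""
    res = stats.linregress(x, y)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        r2 = 1.0  # flat response perfectly reproduced by slope 0
    else:
        pred = res.slope * x + res.intercept
        r2 = 1.0 - float(np.sum((y - pred) ** 2)) / ss_tot
    return float(res.slope), float(res.intercept), min(max(r2, 0.0), 1.0), float(res.stderr)


def fit_critical_speed(efforts: Iterable[tuple[float, float]]) -> CriticalFit:
    """OLS of distance (m) on time (s) over ``(distance_m, time_s)`` pairs."""
    pts = np.asarray(list(efforts), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise FitError("expected (distance_m, time_s) pairs")
    d, t = pts[:, 0], pts[:, 1]
    if np.any(d <= 0) or np.any(t <= 0):
        raise FitError("distances and times must be positive")
    _check_points(t, d)
    slope, intercept, r2, se = _ols(t, d)
    resid = d - (slope * t + intercept)
    return CriticalFit("speed", slope, intercept, r2, int(t.size),
                       tuple(float(r) for r in resid), se)


def fit_critical_hr(efforts: Iterable[tuple[float, float]]) -> CriticalFit:
    """OLS of total heartbeats on time in *minutes* over ``(hb_beats,
    time_s)`` pairs; the slope is the critical heart rate in b·min⁻¹."""
    pts = np.asarray(list(efforts), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise FitError("expected (hb_beats, time_s) pairs")
    hb, t = pts[:, 0], pts[:, 1]
    if np.any(hb < 0) or np.any(t <= 0):
        raise FitError("heartbeats must be non-negative and times positive")
    t_min = t / 60.0
    _check_points(t_min, hb)
    slope, intercept, r2, se = _ols(t_min, hb)
    resid = hb - (slope * t_min + intercept)
    return CriticalFit("hr", slope, intercept, r2, int(t.size),
                       tuple(float(r) for r in resid), se)


def fit_inverse_time_form(efforts: Iterable[tuple[float, float]]) -> CriticalFit:
    """Cross-check fit: mean speed = D′·(1/t) + CS.

    Returns a speed-variant :class:`CriticalFit` whose ``slope`` is CS and
    ``intercept`` is D′ so the two parameterizations are directly
    comparable.  On noiseless collinear data it agrees with
    :func:`fit_critical_speed`; on noisy data it generally differs.
    """
    pts = np.asarray(list(efforts), dtype=float)
    d, t = pts[:, 0], pts[:, 1]
    if np.any(d <= 0) or np.any(t <= 0):
        raise FitError("distances and times must be positive")
    inv_t = 1.0 / t
    _check_points(inv_t, d / t)
    dprime, cs, r2, se = _ols(inv_t, d / t)
    resid = d / t - (dprime * inv_t + cs)
    return CriticalFit("speed", cs, dprime, r2, int(t.size),
                       tuple(float(r) for r in resid), se,
                       parameterization="inverse_time")


def fit_trials(trials: Sequence[EffortTrial]) -> tuple[CriticalFit, CriticalFit]:
    """Fit both models from one participant-session's trials."""
    speed = fit_critical_speed([(tr.distance_m, tr.time_s) for tr in trials])
    hr = fit_critical_hr(
        [(summarize_effort(tr).total_hb_beats, tr.time_s) for tr in trials]
    )
    return speed, hr


def predict_time(fit: CriticalFit, distance_m: float) -> float:
    """Invert the distance–time line: t = (d − D′)/CS, in seconds."""
    if fit.variant != "speed":
        raise TypeError("time prediction requires a speed-variant fit")
    if fit.slope <= 0:
        raise FitError("non-positive critical speed; cannot invert")
    if distance_m <= fit.intercept:
        raise ValueError(
            f"distance {distance_m:g} m does not exceed D' = {fit.intercept:g} m"
        )
    return (distance_m - fit.intercept) / fit.slope


def prescribe_intensity(
    fit: CriticalFit, target_hr_bpm: float, tolerance_bpm: float = 3.0
) -> IntensityPrescription:
    """Classify a target HR against the critical HR.

    Training above CHR accumulates a non-steady-state load (tolerable only
    intermittently); at CHR is the heavy/severe boundary, sustainable roughly
    30–60 min; below CHR is steady-state work.
    """
    if fit.variant != "hr":
        raise TypeError("intensity prescription requires an hr-variant fit")
    chr_bpm = fit.slope
    if abs(target_hr_bpm - chr_bpm) <= tolerance_bpm:
        zone, guidance = "at_chr", (
            "target sits at the critical HR: heavy/severe boundary, "
            "sustainable continuously for roughly 30-60 min"
        )
    elif target_hr_bpm > chr_bpm:
        zone, guidance = "above_chr", (
            "target exceeds the critical HR: severe domain, prescribe "
            "intermittently and monitor closely"
        )
    else:
        zone, guidance = "below_chr", (
            "target is below the critical HR: sustainable continuous exercise"
        )
    return IntensityPrescription(chr_bpm, target_hr_bpm, zone, guidance)


def predicted_hrmax(age_years: float, formula: str = "tanaka") -> float:
    if formula not in HRMAX_FORMULAS:
        raise ConfigError(
            f"unknown HRmax formula {formula!r}; choose from {sorted(HRMAX_FORMULAS)}"
        )
    return HRMAX_FORMULAS[formula](age_years)


def relative_intensity(
    chr_bpm: float, age_years: float, formula: str = "tanaka"
) -> float:
    """CHR as a percentage of the age-predicted maximal HR."""
    if not 18.0 <= age_years <= 100.0:
        raise ValueError("age must lie in [18, 100] years")
    return 100.0 * chr_bpm / predicted_hrmax(age_years, formula)
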