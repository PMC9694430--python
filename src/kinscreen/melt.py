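"""Boltzmann melt-curve fitting for differential scanning fluorimetry (DSF).

A DSF well tracks the fluorescence of an environment-sensitive dye (e.g. SYPRO
Orange) while the protein unfolds along a temperature ramp.  The unfolding
transition is modelled with the four-parameter Boltzmann sigmoid

    F(T) = f_pre + (f_post - f_pre) / (1 + exp((tm - T) / slope))

whose inflection point ``tm`` is the melting temperature.  Real traces decay
after the unfolding peak (the dye dissociates from aggregating protein); the
sigmoid cannot represent that regime, so by default each curve is truncated at
its global fluorescence maximum before fitting — standard DSF practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.special import expit

from .errors import DegenerateCurveError, MalformedInputError

#: Reserved compound identifier for the vehicle (no-ligand) control wells.
DMSO = "DMSO"

_SLOPE_BOUNDS = (0.1, 20.0)  # degC; optimizer box for the transition steepness
_BOUNDARY_TOL = 1e-6  # degC; tm this close to the range edge counts as pinned


def boltzmann(t: np.ndarray | float, f_pre: float, f_post: float, tm: float, slope: float):
    """Evaluate the sigmoid model.  ``expit`` keeps the exponential overflow-safe."""
    return f_pre + (f_post - f_pre) * expit((np.asarray(t, dtype=float) - tm) / slope)


@dataclass(frozen=True)
class MeltCurve:
    """One well's temperature/fluorescence trace with its plate identity.

    Temperatures are degrees Celsius, strictly increasing, at least 10 points
    within [0, 120]; fluorescence is in arbitrary units (AU), same length.
    """

    plate_id: str
    well_id: str
    kinase_id: str
    compound_id: str
    replicate: int
    temperatures: np.ndarray
    fluorescence: np.ndarray
    truncation_temp: float | None = None

    def __post_init__(self):
        t = np.asarray(self.temperatures, dtype=float)
        f = np.asarray(self.fluorescence, dtype=float)
        object.__setattr__(self, "temperatures", t)
        object.__setattr__(self, "fluorescence", f)
        if self.replicate < 1:
            raise MalformedInputError(f"{self.well_id}: replicate must be >= 1")
        if t.ndim != 1 or f.ndim != 1 or len(t) != len(f):
            raise MalformedInputError(f"{self.well_id}: temperature/fluorescence length mismatch")
        if len(t) < 10:
            raise MalformedInputError(f"{self.well_id}: need at least 10 readings, got {len(t)}")
        if not np.all(np.diff(t) > 0):
            raise MalformedInputError(f"{self.well_id}: temperatures must be strictly increasing")
        if t[0] < 0.0 or t[-1] > 120.0:
            raise MalformedInputError(f"{self.well_id}: temperatures outside [0, 120] degC")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(f))):
            raise MalformedInputError(f"{self.well_id}: non-finite readings")

    def __len__(self) -> int:
        return len(self.temperatures)

    @property
    def is_control(self) -> bool:
        return self.compound_id == DMSO


@dataclass(frozen=True)
class FitOptions:
    """Tunable knobs for fitting and QC; defaults are package conventions."""

    min_points: int = 10
    max_iterations: int = 2000
    convergence_tolerance: float = 1e-10
    r_squared_floor: float = 0.9
    truncate_at_peak: bool = True

    def __post_init__(self):
        if self.min_points <= 0 or self.max_iterations <= 0 or self.convergence_tolerance <= 0:
            raise MalformedInputError("fit options must be strictly positive")
        if not 0.0 < self.r_squared_floor <= 1.0:
            raise MalformedInputError("r_squared_floor must lie in (0, 1]")


@dataclass(frozen=True)
class BoltzmannFit:
    """Fitted sigmoid parameters for one well, plus goodness-of-fit."""

    f_pre: float
    f_post: float
    tm: float
    slope: float
    rmse: float
    r_squared: float
    converged: bool
    n_points_used: int
    t_min: float
    t_max: float
    truncation_temp: float | None = None

    @property
    def amplitude(self) -> float:
        return self.f_post - self.f_pre


@dataclass(frozen=True)
class QCVerdict:
    passed: bool
    reasons: tuple[str, ...] = field(default=())

    def __bool__(self) -> bool:
        return self.passed


def truncate_at_max(curve: MeltCurve, min_points: int = 10) -> MeltCurve:
    """Keep the prefix up to and including the global fluorescence maximum.

    Raises :class:`DegenerateCurveError` when fewer than ``min_points``
    readings would remain (e.g. the maximum sits at the first point).
    """
    idx = int(np.argmax(curve.fluorescence))
    if idx + 1 < min_points:
        raise DegenerateCurveError(
            f"{curve.plate_id}/{curve.well_id}: only {idx + 1} points remain after "
            f"truncation at the fluorescence maximum"
        )
    if idx == len(curve) - 1:
        return curve  # no post-peak decay; nothing removed
    return replace(
        curve,
        temperatures=curve.temperatures[: idx + 1],
        fluorescence=curve.fluorescence[: idx + 1],
        truncation_temp=float(curve.temperatures[idx]),
    )


def initial_guess(curve: MeltCurve) -> tuple[float, float, float, float]:
    """Heuristic start values ``(tm0, slope0, f_pre0, f_post0)``.

    ``tm0`` is the midpoint of the steepest rise of the 3-point-smoothed
    trace; a flat trace falls back to the range midpoint (the subsequent fit
    will then be flagged by QC).
    """
    t, f = curve.temperatures, curve.fluorescence
    smooth = f.astype(float).copy()
    smooth[1:-1] = (f[:-2] + f[1:-1] + f[2:]) / 3.0
    diffs = np.diff(smooth) / np.diff(t)
    if np.allclose(diffs, 0.0):
        tm0 = float((t[0] + t[-1]) / 2.0)
    else:
        i = int(np.argmax(diffs))
        tm0 = float((t[i] + t[i + 1]) / 2.0)
    f_pre0 = float(np.mean(f[:5]))
    f_post0 = float(np.mean(f[-5:]))
    return tm0, 2.0, f_pre0, f_post0


def fit_boltzmann(curve: MeltCurve, options: FitOptions = FitOptions()) -> BoltzmannFit:
    """Least-squares Boltzmann fit of one (optionally truncated) melt curve.

    ``tm`` is box-constrained to the observed temperature range and ``slope``
    to (0.1, 20) degC.  Non-convergence or a ``tm`` pinned at a range boundary
    is reported through ``converged=False`` rather than an exception; a
    constant trace raises :class:`DegenerateCurveError`.
    """
    if options.truncate_at_peak:
        curve = truncate_at_max(curve, options.min_points)
    t, f = curve.temperatures, curve.fluorescence
    if len(t) < options.min_points:
        raise DegenerateCurveError(
            f"{curve.plate_id}/{curve.well_id}: {len(t)} points < min_points={options.min_points}"
        )
    if np.ptp(f) == 0.0:
        raise DegenerateCurveError(f"{curve.plate_id}/{curve.well_id}: constant fluorescence")

    t_min, t_max = float(t[0]), float(t[-1])
    tm0, slope0, f_pre0, f_post0 = initial_guess(curve)
    tm0 = float(np.clip(tm0, t_min, t_max))
    span = np.ptp(f)
    lower = [-np.inf, -np.inf, t_min, _SLOPE_BOUNDS[0]]
    upper = [np.inf, np.inf, t_max, _SLOPE_BOUNDS[1]]
    x0 = [f_pre0, max(f_post0, f_pre0 + 1e-9 * max(span, 1.0)), tm0, slope0]

    def residuals(p):
        return boltzmann(t, *p) - f

    result = least_squares(
        residuals,
        x0,
        bounds=(lower, upper),
        max_nfev=options.max_iterations,
        xtol=options.convergence_tolerance,
        ftol=options.convergence_tolerance,
        gtol=options.convergence_tolerance,
    )
    f_pre, f_post, tm, slope = (float(v) for v in result.x)
    resid = result.fun
    rmse = float(np.sqrt(np.mean(resid**2)))
    ss_tot = float(np.sum((f - f.mean()) ** 2))
    r_squared = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 0.0
    pinned = (tm - t_min) < _BOUNDARY_TOL or (t_max - tm) < _BOUNDARY_TOL
    return BoltzmannFit(
        f_pre=f_pre,
        f_post=f_post,
        tm=tm,
        slope=slope,
        rmse=rmse,
        r_squared=min(r_squared, 1.0),
        converged=bool(result.success) and not pinned,
        n_points_used=len(t),
        t_min=t_min,
        t_max=t_max,
        truncation_temp=curve.truncation_temp,
    )


def qc_fit(fit: BoltzmannFit, options: FitOptions = FitOptions()) -> QCVerdict:
    """Accept or reject a fit for downstream delta-Tm analysis.

    Reason codes: ``not-converged`` (optimizer failure or pinned tm),
    ``low-r-squared`` (below ``options.r_squared_floor``), ``tm-at-boundary``,
    ``no-transition`` (non-positive amplitude).
    """
    reasons: list[str] = []
    if not fit.converged:
        reasons.append("not-converged")
    if fit.r_squared < options.r_squared_floor:
        reasons.append("low-r-squared")
    if (fit.tm - fit.t_min) < _BOUNDARY_TOL or (fit.t_max - fit.tm) < _BOUNDARY_TOL:
        reasons.append("tm-at-boundary")
    if fit.f_post <= fit.f_pre:
        reasons.append("no-transition")
    return QCVerdict(passed=not reasons, reasons=tuple(reasons))


def fit_curves(
    curves: Sequence[MeltCurve], options: FitOptions = FitOptions()
) -> list[tuple[MeltCurve, BoltzmannFit | None, QCVerdict]]:
    """Fit a batch of wells; degenerate wells yield ``(curve, None, fail)``."""
    out = []
    for curve in curves:
        try:
            fit = fit_boltzmann(curve, options)
        except DegenerateCurveError:
            out.append((curve, None, QCVerdict(False, ("degenerate-curve",))))
            continue
        out.append((curve, fit, qc_fit(fit, options)))
    return out
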