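"""Per-year parameter estimation with the race-time solvers nested inside.

For each calendar year and sex, the physiological triple (MAP, A, E) is
estimated from the five top-1 running records (200-5000 m) by minimising the
mean absolute relative error between observed and model-solved durations.
The lumped swim pair (K, n) is then estimated from the six top-1 front-crawl
records (50-1500 m) by minimising the mean absolute relative error between
observed and model-solved speeds, holding the year's (MAP, A, E) fixed.

Both objectives wrap a root solve per record, so they are piecewise smooth;
they are minimised with a bounded Nelder-Mead simplex restarted from a small
grid of starting points over the parameter bounds.  The fit is deterministic:
no randomness enters anywhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize

from .core_model import (
    DEFAULT_CONSTANTS,
    AthleteProfile,
    InfeasibleParametersError,
    ModelConstants,
    PhysioParams,
    SwimParams,
    solve_run_time,
    solve_swim_time,
)

__all__ = [
    "PerformanceRecord",
    "FitOptions",
    "FitResult",
    "RUN_DISTANCES",
    "SWIM_DISTANCES",
    "signed_relative_errors",
    "relative_time_error",
    "relative_speed_error",
    "fit_physio",
    "fit_swim",
]

logger = logging.getLogger(__name__)

#: Default competition distance sets, m.
RUN_DISTANCES = (200.0, 400.0, 800.0, 1500.0, 5000.0)
SWIM_DISTANCES = (50.0, 100.0, 200.0, 400.0, 800.0, 1500.0)

_PENALTY = 1e6  # objective value charged when the nested solve is infeasible


@dataclass(frozen=True)
class PerformanceRecord:
    """One top-1 result: the single best time for (year, sex, event)."""

    year: int
    sex: str
    discipline: str  # "run" or "swim"
    distance: float  # m
    time: float  # s

    def __post_init__(self) -> None:
        if self.discipline not in ("run", "swim"):
            raise ValueError(f"discipline must be 'run' or 'swim', got {self.discipline!r}")
        if self.time <= 0:
            raise ValueError(f"time must be positive, got {self.time}")
        if self.distance <= 0:
            raise ValueError(f"distance must be positive, got {self.distance}")

    @property
    def speed(self) -> float:
        return self.distance / self.time


@dataclass(frozen=True)
class FitOptions:
    """Bounds, multi-start grid shape and simplex tolerances.

    ``n_starts`` is the number of grid points per parameter axis; starting
    points are placed at the centres of equal subdivisions of each bound so
    that no start sits on a bound.
    """

    physio_bounds: tuple = ((15.0, 40.0), (500.0, 3000.0), (-10.0, 0.0))
    swim_bounds: tuple = ((1.0, 30.0), (0.25, 4.0))
    n_starts: int = 3
    xatol: float = 1e-8
    fatol: float = 1e-10
    maxiter: int = 2000


DEFAULT_FIT_OPTIONS = FitOptions()


@dataclass
class FitResult:
    """Outcome of one year/sex fit."""

    params: PhysioParams | SwimParams
    objective_value: float  # mean absolute relative error
    per_distance_errors: np.ndarray = field(repr=False)  # signed, one per record
    converged: bool = True
    n_restarts_used: int = 0
    e_weakly_identified: bool = False  # physio fit only: no record beyond t_map

    def __post_init__(self) -> None:
        if self.objective_value < 0:
            raise ValueError("objective_value must be non-negative")


# ---------------------------------------------------------------------------
# Error measures
# ---------------------------------------------------------------------------

def signed_relative_errors(
    estimated: Sequence[float], observed: Sequence[float]
) -> np.ndarray:
    """Element-wise (estimated - observed) / observed."""
    est = np.asarray(estimated, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if est.shape != obs.shape:
        raise ValueError(f"length mismatch: {est.shape} vs {obs.shape}")
    if np.any(obs <= 0):
        raise ValueError("observed values must be positive")
    return (est - obs) / obs


def relative_time_error(
    estimated: Sequence[float], observed: Sequence[float]
) -> float:
    """Mean absolute relative error between estimated and observed durations.

    The signed per-element errors are available via
    :func:`signed_relative_errors`.
    """
    return float(np.mean(np.abs(signed_relative_errors(estimated, observed))))


def relative_speed_error(
    estimated: Sequence[float], observed: Sequence[float]
) -> float:
    """Mean absolute relative error between estimated and observed speeds."""
    return relative_time_error(estimated, observed)


# ---------------------------------------------------------------------------
# Multi-start scaffolding
# ---------------------------------------------------------------------------

def _start_grid(bounds: Sequence[tuple[float, float]], n: int) -> np.ndarray:
    """Cartesian grid of starts at the centres of n equal subdivisions."""
    axes = []
    for lo, hi in bounds:
        edges = np.linspace(lo, hi, n + 1)
        axes.append(0.5 * (edges[:-1] + edges[1:]))
    mesh = np.meshgrid(*axes, indexing="ij")
    return np.stack([m.ravel() for m in mesh], axis=1)


def _multistart_minimize(objective, bounds, options: FitOptions):
    starts = _start_grid(bounds, options.n_starts)
    best = None
    for x0 in starts:
        res = minimize(
            objective,
            x0,
            method="Nelder-Mead",
            bounds=bounds,
            options=dict(
                xatol=options.xatol,
                fatol=options.fatol,
                maxiter=options.maxiter,
                maxfev=options.maxiter,
            ),
        )
        if best is None or res.fun < best.fun:
            best = res
    logger.debug(
        "multi-start minimize: %d starts, best objective %.3e, converged=%s",
        len(starts), best.fun, best.success,
    )
    return best, len(starts)


# ---------------------------------------------------------------------------
# Fits
# ---------------------------------------------------------------------------

def _check_records(records: Sequence[PerformanceRecord], discipline: str, n_min: int):
    if len(records) < n_min:
        raise ValueError(
            f"need at least {n_min} {discipline} records, got {len(records)}"
        )
    for r in records:
        if r.discipline != discipline:
            raise ValueError(f"expected {discipline} records, got {r.discipline!r}")
    keys = {(r.year, r.sex, r.distance) for r in records}
    if len(keys) != len(records):
        raise ValueError("duplicate (year, sex, distance) among records")


def fit_physio(
    records: Sequence[PerformanceRecord],
    profile: AthleteProfile,
    constants: ModelConstants = DEFAULT_CONSTANTS,
    options: FitOptions = DEFAULT_FIT_OPTIONS,
) -> FitResult:
    """Estimate (MAP, A, E) from one year's running records.

    Minimises the mean absolute relative duration error with the run-time
    solver nested in the objective.  E is only identified by records longer
    than t_map; if none is present the fit proceeds but the result carries
    ``e_weakly_identified=True``.
    """
    _check_records(records, "run", 3)
    distances = np.array([r.distance for r in records])
    observed = np.array([r.time for r in records])

    if not any(r.time > constants.t_map for r in records):
        weak_e = True
        logger.warning("no record beyond t_map=%g s: E is weakly identified", constants.t_map)
    else:
        weak_e = False

    def objective(x: np.ndarray) -> float:
        physio = PhysioParams(x[0], x[1], min(x[2], 0.0))
        try:
            est = [solve_run_time(d, physio, profile, constants) for d in distances]
        except InfeasibleParametersError:
            return _PENALTY
        return relative_time_error(est, observed)

    best, n_starts = _multistart_minimize(objective, options.physio_bounds, options)
    physio = PhysioParams(best.x[0], best.x[1], min(best.x[2], 0.0))
    est = np.array([solve_run_time(d, physio, profile, constants) for d in distances])
    return FitResult(
        params=physio,
        objective_value=float(best.fun),
        per_distance_errors=signed_relative_errors(est, observed),
        converged=bool(best.success),
        n_restarts_used=n_starts,
        e_weakly_identified=weak_e,
    )


def fit_swim(
    records: Sequence[PerformanceRecord],
    physio: PhysioParams,
    profile: AthleteProfile,
    constants: ModelConstants = DEFAULT_CONSTANTS,
    options: FitOptions = DEFAULT_FIT_OPTIONS,
) -> FitResult:
    """Estimate (K, n) from one year's swimming records.

    The year's (MAP, A, E) from the running fit are held fixed; the objective
    is the mean absolute relative error between observed speeds (distance /
    top-1 time) and speeds implied by the swim-time solver.
    """
    _check_records(records, "swim", 2)
    distances = np.array([r.distance for r in records])
    observed_v = np.array([r.speed for r in records])

    def objective(x: np.ndarray) -> float:
        swim = SwimParams(x[0], x[1])
        try:
            est_t = [solve_swim_time(d, physio, swim, profile, constants) for d in distances]
        except InfeasibleParametersError:
            return _PENALTY
        return relative_speed_error(distances / np.array(est_t), observed_v)

    best, n_starts = _multistart_minimize(objective, options.swim_bounds, options)
    swim = SwimParams(best.x[0], best.x[1])
    est_t = np.array([solve_swim_time(d, physio, swim, profile, constants) for d in distances])
    return FitResult(
        params=swim,
        objective_value=float(best.fun),
        per_distance_errors=signed_relative_errors(distances / est_t, observed_v),
        converged=bool(best.success),
        n_restarts_used=n_starts,
    )
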