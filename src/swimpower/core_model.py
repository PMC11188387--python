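"""Closed-form power supply and demand models and the race-time solvers.

The supply side is an endurance bioenergetics model in the Péronnet–Thibault
lineage: the metabolic power a prototypical athlete can sustain for a duration
``t`` is the sum of a basal floor (BMR), an aerobic term that rises with first
order kinetics (time constant ``k1``) towards the relative maximal aerobic
power ``B = MAP - BMR``, and an anaerobic term that releases a finite energy
store ``S`` with time constant ``k2``.  Both ``B`` and ``S`` are constant up to
the longest duration for which maximal intensity can be held (``t_map``,
~420 s) and decline logarithmically beyond it.

The demand side is sport specific.  For running the metabolic power needed to
hold speed ``v`` over distance ``d`` is an explicit cost model (basal + linear
locomotion cost + cubic aerodynamic drag + kinetic-energy amortisation).  For
front-crawl swimming the drag force, propelling efficiency and gross
efficiency are not separately identifiable from top-list times, so demand is a
lumped power law ``K * v**(n + 1)``.

Record times are the durations at which supply equals demand; both balances
are solved with bracketed Brent root finding over physical speed limits.

All powers are mass-specific (W/kg) and all energies are J/kg.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from scipy.optimize import brentq

__all__ = [
    "AthleteProfile",
    "ModelConstants",
    "PhysioParams",
    "SwimParams",
    "DomainError",
    "InfeasibleParametersError",
    "MALE",
    "FEMALE",
    "DEFAULT_CONSTANTS",
    "running_demand_power",
    "aerobic_capacity_term",
    "anaerobic_capacity_term",
    "available_power",
    "swim_demand_power",
    "solve_run_time",
    "solve_swim_time",
]


class DomainError(ValueError):
    """An argument lies outside the physical domain of the model."""


class InfeasibleParametersError(RuntimeError):
    """Supply and demand do not cross within the physical speed bracket."""


@dataclass(frozen=True)
class AthleteProfile:
    """Prototypical athlete constants.

    Parameters
    ----------
    sex : {"male", "female"}
    bmr : basal metabolic rate, W/kg.
    mass : body mass, kg.
    bsa : body surface area, m^2.
    """

    sex: str
    bmr: float = 1.2
    mass: float = 70.0
    bsa: float = 1.80

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise DomainError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if self.bmr <= 0 or self.mass <= 0 or self.bsa <= 0:
            raise DomainError("bmr, mass and bsa must all be positive")


#: Standardised prototypical athletes (BMR 1.2 W/kg for both sexes).
MALE = AthleteProfile("male", bmr=1.2, mass=70.0, bsa=1.80)
FEMALE = AthleteProfile("female", bmr=1.2, mass=60.0, bsa=1.60)


@dataclass(frozen=True)
class ModelConstants:
    """Kinetic constants of the supply model.

    k1, k2 : aerobic / anaerobic onset time constants, s.
    t_map : longest duration maximal intensity can be held, s.
    f : rate of logarithmic decline of the anaerobic store beyond t_map.
    """

    k1: float = 30.0
    k2: float = 20.0
    t_map: float = 420.0
    f: float = -0.233

    def __post_init__(self) -> None:
        if self.k1 <= 0 or self.k2 <= 0 or self.t_map <= 0:
            raise DomainError("k1, k2 and t_map must be positive")


DEFAULT_CONSTANTS = ModelConstants()


@dataclass(frozen=True)
class PhysioParams:
    """Fitted physiological triple for one year and sex.

    map : maximal aerobic power, W/kg.
    a_cap : anaerobic capacity A, J/kg.
    e_decay : decline of maximal aerobic power per ln(time) beyond t_map,
        W/kg (non-positive in practice; a positive value is allowed but
        warned about, since it implies power that grows with duration).
    """

    map: float
    a_cap: float
    e_decay: float

    def __post_init__(self) -> None:
        if self.map <= 0:
            raise DomainError("map must be positive")
        if self.a_cap <= 0:
            raise DomainError("a_cap must be positive")
        if self.e_decay > 0:
            warnings.warn(
                f"e_decay = {self.e_decay:g} is positive; aerobic power would "
                "increase with duration beyond t_map",
                stacklevel=2,
            )


@dataclass(frozen=True)
class SwimParams:
    """Lumped swim power-law pair for one year and sex.

    k_coef : coefficient K absorbing active drag, propelling efficiency and
        gross efficiency, W/kg per (m/s)^(n+1).
    n_exp : drag exponent n (metabolic power scales as v^(n+1)).
    """

    k_coef: float
    n_exp: float

    def __post_init__(self) -> None:
        if self.k_coef <= 0:
            raise DomainError("k_coef must be positive")
        if self.n_exp <= 0:
            raise DomainError("n_exp must be positive")


# ---------------------------------------------------------------------------
# Demand
# ---------------------------------------------------------------------------

def running_demand_power(v: float, d: float, profile: AthleteProfile) -> float:
    """Metabolic power (W/kg) required to run distance ``d`` at speed ``v``.

    BMR + 3.86 v + 0.4 (BSA/m) v^3 + v^3 / (2 d): basal floor, locomotion
    cost linear in speed, aerodynamic drag cubic in speed, and the kinetic
    energy v^2/2 amortised over the race duration d/v.
    """
    if v <= 0:
        raise DomainError(f"speed must be positive, got {v}")
    if d <= 0:
        raise DomainError(f"distance must be positive, got {d}")
    v3 = v * v * v
    return profile.bmr + 3.86 * v + 0.4 * (profile.bsa / profile.mass) * v3 + v3 / (2.0 * d)


def swim_demand_power(v: float, swim: SwimParams) -> float:
    """Metabolic power (W/kg) demanded by front-crawl swimming at speed ``v``.

    The lumped power law K * v^(n+1).
    """
    if v <= 0:
        raise DomainError(f"speed must be positive, got {v}")
    return swim.k_coef * v ** (swim.n_exp + 1.0)


# ---------------------------------------------------------------------------
# Supply
# ---------------------------------------------------------------------------

def aerobic_capacity_term(
    t: float,
    physio: PhysioParams,
    profile: AthleteProfile,
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> float:
    """Relative maximal aerobic power B(t) = MAP - BMR, W/kg.

    Constant up to t_map, then declining as E * ln(t / t_map); continuous at
    t_map because ln(1) = 0.
    """
    if t <= 0:
        raise DomainError(f"duration must be positive, got {t}")
    b = physio.map - profile.bmr
    if t > constants.t_map:
        b += physio.e_decay * math.log(t / constants.t_map)
    return b


def anaerobic_capacity_term(
    t: float,
    physio: PhysioParams,
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> float:
    """Available anaerobic energy S(t), J/kg.

    S = A up to t_map, then A * (1 + f * ln(t / t_map)) with f < 0.
    """
    if t <= 0:
        raise DomainError(f"duration must be positive, got {t}")
    s = physio.a_cap
    if t > constants.t_map:
        s *= 1.0 + constants.f * math.log(t / constants.t_map)
    return s


def available_power(
    t: float,
    physio: PhysioParams,
    profile: AthleteProfile,
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> float:
    """Sustainable metabolic power (W/kg) for an all-out effort of duration t.

    BMR + B(t) * [1 + (k1/t)(exp(-t/k1) - 1)] + (S(t)/t)(1 - exp(-t/k2)).
    The bracketed factors account for the finite onset kinetics of aerobic
    and anaerobic metabolism at the start of exercise.
    """
    if t <= 0:
        raise DomainError(f"duration must be positive, got {t}")
    b = aerobic_capacity_term(t, physio, profile, constants)
    s = anaerobic_capacity_term(t, physio, constants)
    aerobic = b * (1.0 + (constants.k1 / t) * (math.exp(-t / constants.k1) - 1.0))
    anaerobic = (s / t) * (1.0 - math.exp(-t / constants.k2))
    return profile.bmr + aerobic + anaerobic


# ---------------------------------------------------------------------------
# Solvers
# ---------------------------------------------------------------------------

_BRENT_KW = dict(xtol=1e-12, rtol=8.9e-16, maxiter=200)


def _bracketed_root(g, t_lo: float, t_hi: float, d: float, what: str) -> float:
    """Brent root of ``g`` on [t_lo, t_hi], expanding the bracket once by x2."""
    g_lo, g_hi = g(t_lo), g(t_hi)
    if g_lo * g_hi > 0:
        t_lo, t_hi = t_lo / 2.0, t_hi * 2.0
        g_lo, g_hi = g(t_lo), g(t_hi)
        if g_lo * g_hi > 0:
            raise InfeasibleParametersError(
                f"infeasible parameters: supply-demand balance has no root for "
                f"{what} distance d={d:g} m on t in [{t_lo:g}, {t_hi:g}] s"
            )
    if g_lo == 0.0:
        return t_lo
    if g_hi == 0.0:
        return t_hi
    return brentq(g, t_lo, t_hi, **_BRENT_KW)


def solve_run_time(
    d: float,
    physio: PhysioParams,
    profile: AthleteProfile,
    constants: ModelConstants = DEFAULT_CONSTANTS,
    speed_bracket: tuple[float, float] = (0.5, 12.0),
) -> float:
    """Race duration t* (s) at which running supply equals demand over ``d``.

    The balance available_power(t) - running_demand_power(d/t, d) is strictly
    monotone in t over the physical bracket (speeds between ``speed_bracket``
    limits, default 0.5-12 m/s), so the root is unique.
    """
    if d <= 0:
        raise DomainError(f"distance must be positive, got {d}")
    v_lo, v_hi = speed_bracket

    def g(t: float) -> float:
        return available_power(t, physio, profile, constants) - running_demand_power(
            d / t, d, profile
        )

    return _bracketed_root(g, d / v_hi, d / v_lo, d, "running")


def solve_swim_time(
    d: float,
    physio: PhysioParams,
    swim: SwimParams,
    profile: AthleteProfile,
    constants: ModelConstants = DEFAULT_CONSTANTS,
    speed_bracket: tuple[float, float] = (0.5, 4.0),
) -> float:
    """Race duration t* (s) at which swim demand K (d/t)^(n+1) meets supply."""
    if d <= 0:
        raise DomainError(f"distance must be positive, got {d}")
    v_lo, v_hi = speed_bracket

    def g(t: float) -> float:
        return available_power(t, physio, profile, constants) - swim_demand_power(
            d / t, swim
        )

    return _bracketed_root(g, d / v_hi, d / v_lo, d, "swimming")
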