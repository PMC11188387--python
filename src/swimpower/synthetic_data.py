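"""Synthetic yearly top-1 record generator.

The analysis consumes one best time per (year, sex, event) extracted from
public top-lists.  This module fabricates tables with the same statistical
structure: the underlying physiology and swim-drag parameters drift linearly
over the years (emulating the slow secular trends the real series show, e.g.
a MAP slope of a few hundredths of a W/kg per year), the model is solved
forward for the record time of each event, and small multiplicative
lognormal noise (default 0.5% relative, the scale of the fit residuals the
pipeline reports) perturbs each time independently.

Only top-1 values are generated; there is no athlete-population model, no
swimsuit-era discontinuity and no pool/turn structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .core_model import (
    DEFAULT_CONSTANTS,
    FEMALE,
    MALE,
    AthleteProfile,
    InfeasibleParametersError,
    ModelConstants,
    PhysioParams,
    SwimParams,
    solve_run_time,
    solve_swim_time,
)
from .fitting import RUN_DISTANCES, SWIM_DISTANCES, DEFAULT_FIT_OPTIONS

__all__ = [
    "ParamDrift",
    "TrajectoryConfig",
    "generate_true_params",
    "generate_toplists",
    "noise_free",
    "PROFILES",
]

logger = logging.getLogger(__name__)

#: Profiles keyed by the record-table sex code.
PROFILES: Mapping[str, AthleteProfile] = {"M": MALE, "F": FEMALE}


@dataclass(frozen=True)
class ParamDrift:
    """Linear drift of one parameter: value(year) = start + slope*(year - year0)."""

    start: float
    slope: float = 0.0

    def at(self, year: int, year0: int) -> float:
        return self.start + self.slope * (year - year0)


def _default_drifts() -> dict:
    # Scales mirror the fitted series: flat male physiology around the
    # all-years forecasts, a slowly rising female MAP and falling female A,
    # and gently drifting drag parameters.
    return {
        "M": {
            "map": ParamDrift(29.68, 0.0),
            "a": ParamDrift(1653.03, 0.0),
            "e": ParamDrift(-1.96, 0.0),
            "k": ParamDrift(8.29, 0.02),
            "n": ParamDrift(1.50, -0.01),
        },
        "F": {
            "map": ParamDrift(25.71, 0.028),
            "a": ParamDrift(1528.96, -0.81),
            "e": ParamDrift(-0.87, 0.0),
            "k": ParamDrift(7.79, -0.01),
            "n": ParamDrift(1.648, -0.002),
        },
    }


@dataclass(frozen=True)
class TrajectoryConfig:
    """Study conditions for one synthetic dataset.

    drifts: per sex code ("M"/"F"), per parameter ("map", "a", "e", "k", "n"),
    a :class:`ParamDrift` anchored at ``year_start``.  ``noise_sd`` is the
    standard deviation of the lognormal multiplicative noise on times.
    """

    year_start: int = 1995
    year_end: int = 2023
    drifts: Mapping[str, Mapping[str, ParamDrift]] = field(default_factory=_default_drifts)
    noise_sd: float = 0.005
    seed: int = 0
    run_distances: tuple = RUN_DISTANCES
    swim_distances: tuple = SWIM_DISTANCES

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.year_end - self.year_start + 1 < 3:
            raise ValueError("year range must span at least 3 years")

    @property
    def years(self) -> range:
        return range(self.year_start, self.year_end + 1)

    def to_dict(self) -> dict:
        return {
            "year_start": self.year_start,
            "year_end": self.year_end,
            "noise_sd": self.noise_sd,
            "seed": self.seed,
            "run_distances": list(self.run_distances),
            "swim_distances": list(self.swim_distances),
            "drifts": {
                sex: {p: [d.start, d.slope] for p, d in by_sex.items()}
                for sex, by_sex in self.drifts.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrajectoryConfig":
        drifts = {
            sex: {p: ParamDrift(*pair) for p, pair in by_sex.items()}
            for sex, by_sex in d.get("drifts", {}).items()
        }
        return cls(
            year_start=d["year_start"],
            year_end=d["year_end"],
            drifts=drifts or _default_drifts(),
            noise_sd=d.get("noise_sd", 0.005),
            seed=d.get("seed", 0),
            run_distances=tuple(d.get("run_distances", RUN_DISTANCES)),
            swim_distances=tuple(d.get("swim_distances", SWIM_DISTANCES)),
        )


def generate_true_params(
    config: TrajectoryConfig,
) -> dict[tuple[int, str], tuple[PhysioParams, SwimParams]]:
    """Noise-free parameter trajectories, keyed by (year, sex code).

    Deterministic given the config.  Raises if a drift pushes any parameter
    outside the fitting bounds, naming the offending year.
    """
    (map_b, a_b, e_b) = DEFAULT_FIT_OPTIONS.physio_bounds
    (k_b, n_b) = DEFAULT_FIT_OPTIONS.swim_bounds
    bounds = {"map": map_b, "a": a_b, "e": e_b, "k": k_b, "n": n_b}
    out = {}
    for sex, by_sex in config.drifts.items():
        for year in config.years:
            vals = {p: d.at(year, config.year_start) for p, d in by_sex.items()}
            for p, v in vals.items():
                lo, hi = bounds[p]
                if not (lo <= v <= hi):
                    raise ValueError(
                        f"drift pushes {p!r} to {v:g} outside bounds [{lo:g}, {hi:g}] "
                        f"in year {year} for sex {sex!r}"
                    )
            out[(year, sex)] = (
                PhysioParams(vals["map"], vals["a"], vals["e"]),
                SwimParams(vals["k"], vals["n"]),
            )
    return out


def generate_toplists(
    true_params: Mapping[tuple[int, str], tuple[PhysioParams, SwimParams]],
    config: TrajectoryConfig,
    profiles: Mapping[str, AthleteProfile] = PROFILES,
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> pd.DataFrame:
    """Model-solved top-1 times with multiplicative noise, as a record table.

    Columns: year, sex, discipline, distance_m, time_s — the same dialect the
    reader accepts.  time = solved time * exp(eps), eps ~ N(0, noise_sd),
    independent across rows; seeded by ``config.seed`` and bit-reproducible.
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    for (year, sex) in sorted(true_params):
        physio, swim = true_params[(year, sex)]
        profile = profiles[sex]
        try:
            for d in config.run_distances:
                rows.append((year, sex, "run", d, solve_run_time(d, physio, profile, constants)))
            for d in config.swim_distances:
                rows.append((year, sex, "swim", d, solve_swim_time(d, physio, swim, profile, constants)))
        except InfeasibleParametersError as err:
            raise InfeasibleParametersError(f"year {year}, sex {sex}: {err}") from err
    df = pd.DataFrame(rows, columns=["year", "sex", "discipline", "distance_m", "time_s"])
    if config.noise_sd > 0:
        df["time_s"] *= np.exp(rng.normal(0.0, config.noise_sd, size=len(df)))
    logger.info(
        "generated %d synthetic records for %d years, seed=%d, noise_sd=%g",
        len(df), len(config.years), config.seed, config.noise_sd,
    )
    return df


def noise_free(config: TrajectoryConfig) -> TrajectoryConfig:
    """The same study conditions with the noise switched off."""
    return replace(config, noise_sd=0.0)
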