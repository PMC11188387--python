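"""Shared fixtures: published 2024 forecast tables and reference parameters.

The printed tables (2024 parameter forecasts, 2024 predicted race times and
the standing world records at the end of 2023) are inputs to the arithmetic
and consistency checks; they are transcribed here once.
"""

from pathlib import Path

import pytest
from hypothesis import settings

from swimpower import MALE, PhysioParams, SwimParams

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

DATA_DIR = Path(__file__).parent / "data"

#: 2024 physiological forecasts (MAP W/kg, E W/kg, A J/kg) per year subset/sex.
PHYSIO_2024 = {
    ("all", "M"): PhysioParams(map=29.68, a_cap=1653.03, e_decay=-1.96),
    ("all", "F"): PhysioParams(map=26.52, a_cap=1505.47, e_decay=-0.87),
    ("olympic", "M"): PhysioParams(map=29.50, a_cap=1666.24, e_decay=-1.68),
    ("olympic", "F"): PhysioParams(map=26.69, a_cap=1526.20, e_decay=-0.87),
}

#: 2024 lumped drag forecasts (K, n) per year subset/sex.
SWIM_2024 = {
    ("all", "M"): SwimParams(k_coef=8.87, n_exp=1.21),
    ("all", "F"): SwimParams(k_coef=7.50, n_exp=1.59),
    ("olympic", "M"): SwimParams(k_coef=9.03, n_exp=1.17),
    ("olympic", "F"): SwimParams(k_coef=7.79, n_exp=1.64),
}

_DISTANCES = (50.0, 100.0, 200.0, 400.0, 800.0, 1500.0)


def _by_distance(times):
    return dict(zip(_DISTANCES, times))


#: Standing world records at the end of 2023 and the published 2024 forecasts, s.
WORLD_RECORDS = {
    "M": _by_distance((20.91, 46.86, 102.00, 220.07, 452.12, 871.02)),
    "F": _by_distance((23.61, 51.71, 112.85, 235.38, 484.79, 920.48)),
}
FORECAST_TIMES = {
    ("all", "M"): _by_distance((20.95, 46.88, 103.98, 219.49, 451.93, 878.42)),
    ("olympic", "M"): _by_distance((20.72, 46.51, 103.61, 219.26, 451.93, 876.75)),
    ("all", "F"): _by_distance((23.48, 51.77, 112.63, 235.31, 482.37, 923.79)),
    ("olympic", "F"): _by_distance((24.09, 53.07, 115.20, 240.41, 492.74, 943.13)),
}


@pytest.fixture(scope="session")
def male_all_physio():
    return PHYSIO_2024[("all", "M")]


@pytest.fixture(scope="session")
def male_all_swim():
    return SWIM_2024[("all", "M")]


@pytest.fixture(scope="session")
def male_profile():
    return MALE


@pytest.fixture(scope="session")
def wr_csv_path():
    return DATA_DIR / "world_records_2023.csv"


@pytest.fixture(scope="session")
def monte_carlo_fits():
    """200 replicate fits of one year's records under 0.5% multiplicative noise.

    Each replicate perturbs the noise-free model-solved top-1 times with
    independent lognormal noise (sd 0.005, the generator's default) and
    re-fits (MAP, A, E) and then (K, n).  Shared across tests because it is
    by far the most expensive fixture.
    """
    import numpy as np

    from swimpower import (
        DEFAULT_CONSTANTS,
        RUN_DISTANCES,
        SWIM_DISTANCES,
        FitOptions,
        PerformanceRecord,
        fit_physio,
        fit_swim,
        solve_run_time,
        solve_swim_time,
    )

    physio_true = PHYSIO_2024[("all", "M")]
    swim_true = SWIM_2024[("all", "M")]
    run_clean = [solve_run_time(d, physio_true, MALE, DEFAULT_CONSTANTS) for d in RUN_DISTANCES]
    swim_clean = [
        solve_swim_time(d, physio_true, swim_true, MALE, DEFAULT_CONSTANTS)
        for d in SWIM_DISTANCES
    ]
    rng = np.random.default_rng(1234)
    opts = FitOptions(n_starts=1)
    noise_sd = 0.005
    rows = []
    for _ in range(200):
        run_recs = [
            PerformanceRecord(2020, "M", "run", d, t * np.exp(rng.normal(0, noise_sd)))
            for d, t in zip(RUN_DISTANCES, run_clean)
        ]
        swim_recs = [
            PerformanceRecord(2020, "M", "swim", d, t * np.exp(rng.normal(0, noise_sd)))
            for d, t in zip(SWIM_DISTANCES, swim_clean)
        ]
        fr = fit_physio(run_recs, MALE, DEFAULT_CONSTANTS, opts)
        fs = fit_swim(swim_recs, fr.params, MALE, DEFAULT_CONSTANTS, opts)
        rows.append(
            dict(
                map=fr.params.map,
                a=fr.params.a_cap,
                e=fr.params.e_decay,
                k=fs.params.k_coef,
                n=fs.params.n_exp,
                run_obj=fr.objective_value,
                swim_obj=fs.objective_value,
            )
        )
    return {"truth": (physio_true, swim_true), "noise_sd": noise_sd, "rows": rows}
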