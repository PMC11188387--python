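"""Supply/demand model values, continuity, monotonicity and solver contracts."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from swimpower import (
    DEFAULT_CONSTANTS,
    FEMALE,
    MALE,
    DomainError,
    InfeasibleParametersError,
    PhysioParams,
    SwimParams,
    aerobic_capacity_term,
    anaerobic_capacity_term,
    available_power,
    running_demand_power,
    solve_run_time,
    solve_swim_time,
    swim_demand_power,
)

C = DEFAULT_CONSTANTS


class TestRunningDemand:
    def test_vanishing_speed_approaches_bmr(self):
        assert running_demand_power(1e-9, 400.0, MALE) == pytest.approx(1.2, abs=1e-6)

    def test_unit_speed_without_kinetic_term(self):
        # v = 1 m/s, distance so long the kinetic amortisation vanishes:
        # 1.2 + 3.86 + 0.4 * (1.8 / 70)
        assert running_demand_power(1.0, 1e15, MALE) == pytest.approx(5.070285714, rel=1e-9)

    def test_cubic_terms_scale_by_eight_when_speed_doubles(self):
        for v in (1.0, 2.5, 4.0):
            cubic = lambda u: running_demand_power(u, 800.0, MALE) - MALE.bmr - 3.86 * u
            assert cubic(2 * v) == pytest.approx(8 * cubic(v), rel=1e-12)

    def test_strictly_increasing_in_speed(self):
        v = np.linspace(0.5, 12.0, 400)
        p = [running_demand_power(x, 1500.0, FEMALE) for x in v]
        assert np.all(np.diff(p) > 0)

    @pytest.mark.parametrize("v,d", [(0.0, 400.0), (-1.0, 400.0), (3.0, 0.0), (3.0, -5.0)])
    def test_domain_errors(self, v, d):
        with pytest.raises(DomainError):
            running_demand_power(v, d, MALE)


class TestCapacityTerms:
    def test_aerobic_at_t_map_is_map_minus_bmr(self, male_all_physio):
        b = aerobic_capacity_term(C.t_map, male_all_physio, MALE, C)
        assert b == pytest.approx(male_all_physio.map - MALE.bmr, rel=1e-14)

    def test_aerobic_log_decline_beyond_t_map(self, male_all_physio):
        # 28.48 - 1.96 * ln(451.93 / 420)
        b = aerobic_capacity_term(451.93, male_all_physio, MALE, C)
        assert b == pytest.approx(28.48 - 1.96 * math.log(451.93 / 420.0), rel=1e-12)
        assert b == pytest.approx(28.336, abs=5e-4)

    def test_zero_decay_gives_flat_aerobic_term(self):
        ph = PhysioParams(30.0, 1500.0, 0.0)
        for t in (10, 420, 1000, 3600):
            assert aerobic_capacity_term(t, ph, MALE, C) == pytest.approx(28.8, rel=1e-12)

    def test_anaerobic_constant_below_t_map(self, male_all_physio):
        for t in (5.0, 100.0, C.t_map):
            assert anaerobic_capacity_term(t, male_all_physio, C) == 1653.03

    def test_anaerobic_log_decline(self, male_all_physio):
        s = anaerobic_capacity_term(451.93, male_all_physio, C)
        assert s == pytest.approx(1653.03 * (1 - 0.233 * math.log(451.93 / 420.0)), rel=1e-12)
        assert s == pytest.approx(1624.8, abs=0.1)


class TestAvailablePower:
    def test_reference_value(self, male_all_physio):
        assert available_power(219.49, male_all_physio, MALE, C) == pytest.approx(
            33.32, abs=5e-3
        )

    def test_continuity_at_t_map(self, male_all_physio):
        eps = 1e-9
        lo = available_power(C.t_map - eps, male_all_physio, MALE, C)
        hi = available_power(C.t_map + eps, male_all_physio, MALE, C)
        assert abs(hi - lo) < 1e-9

    def test_negligible_anaerobic_store_keeps_power_below_map(self):
        ph = PhysioParams(30.0, 1e-12, -2.0)
        for t in (30.0, 120.0, 420.0, 1200.0):
            assert available_power(t, ph, MALE, C) < ph.map

    @pytest.mark.parametrize(
        "physio",
        [
            PhysioParams(15.0, 500.0, -10.0),
            PhysioParams(29.68, 1653.03, -1.96),
            PhysioParams(40.0, 3000.0, -1e-9),
            PhysioParams(22.0, 1200.0, -5.0),
        ],
    )
    def test_strictly_decreasing_on_race_durations(self, physio):
        t = np.linspace(60.0, 3600.0, 2000)
        p = [available_power(x, physio, MALE, C) for x in t]
        assert np.all(np.diff(p) < 0)

    def test_rejects_non_positive_duration(self, male_all_physio):
        with pytest.raises(DomainError):
            available_power(0.0, male_all_physio, MALE, C)


class TestSwimDemand:
    def test_unit_speed_returns_coefficient(self):
        assert swim_demand_power(1.0, SwimParams(8.87, 1.21)) == 8.87

    def test_reference_value(self, male_all_swim):
        assert swim_demand_power(1.82, male_all_swim) == pytest.approx(33.3, abs=0.05)

    @given(
        v=st.floats(0.3, 3.0),
        c=st.floats(0.5, 3.0),
        n=st.floats(0.3, 3.5),
    )
    @settings(deadline=None, max_examples=60)
    def test_power_law_homogeneity(self, v, c, n):
        sw = SwimParams(5.0, n)
        assert swim_demand_power(c * v, sw) == pytest.approx(
            c ** (n + 1) * swim_demand_power(v, sw), rel=1e-10
        )


def _balance_residual(t, d, male_all_physio, demand):
    supply = available_power(t, male_all_physio, MALE, C)
    return abs(supply - demand(d / t)) / supply


class TestSolvers:
    def test_run_solution_balances_supply_and_demand(self, male_all_physio):
        for d in (200.0, 400.0, 800.0, 1500.0, 5000.0):
            t = solve_run_time(d, male_all_physio, MALE, C)
            res = _balance_residual(t, d, male_all_physio, lambda v: running_demand_power(v, d, MALE))
            assert res <= 1e-10

    def test_swim_solution_balances_supply_and_demand(self, male_all_physio, male_all_swim):
        for d in (50.0, 400.0, 1500.0):
            t = solve_swim_time(d, male_all_physio, male_all_swim, MALE, C)
            res = _balance_residual(t, d, male_all_physio, lambda v: swim_demand_power(v, male_all_swim))
            assert res <= 1e-10

    def test_run_time_increases_with_distance(self, male_all_physio):
        times = [solve_run_time(d, male_all_physio, MALE, C) for d in (200, 400, 800, 1500, 5000)]
        assert np.all(np.diff(times) > 0)

    def test_higher_map_runs_faster(self):
        maps = np.linspace(20.0, 38.0, 8)
        times = [
            solve_run_time(1500.0, PhysioParams(m, 1653.03, -1.96), MALE, C) for m in maps
        ]
        assert np.all(np.diff(times) < 0)

    def test_more_resistive_medium_swims_slower(self, male_all_physio):
        ks = [6.0, 8.0, 10.0, 14.0]
        times = [
            solve_swim_time(400.0, male_all_physio, SwimParams(k, 1.21), MALE, C) for k in ks
        ]
        assert np.all(np.diff(times) > 0)

    def test_infeasible_parameters_name_the_distance(self, male_all_physio):
        with pytest.raises(InfeasibleParametersError, match="1500"):
            solve_swim_time(1500.0, male_all_physio, SwimParams(5000.0, 1.21), MALE, C)

    def test_root_matches_exhaustive_sign_change_scan(self, male_all_physio):
        """Brent root vs an independent fine scan of the supply-demand sign change.

        The oracle re-implements both sides vectorised in numpy and locates
        the sign change by brute force at 1e-4 s resolution (coarse-to-fine).
        """
        rng = np.random.default_rng(20240)

        def supply(t, mapv, a, e):
            b = np.where(t > C.t_map, mapv - 1.2 + e * np.log(t / C.t_map), mapv - 1.2)
            s = np.where(t > C.t_map, a * (1 + C.f * np.log(t / C.t_map)), a)
            return 1.2 + b * (1 + (C.k1 / t) * (np.exp(-t / C.k1) - 1)) + (s / t) * (
                1 - np.exp(-t / C.k2)
            )

        for _ in range(100):
            mapv = rng.uniform(20, 38)
            a = rng.uniform(800, 2500)
            e = rng.uniform(-6, -0.2)
            k = rng.uniform(5, 12)
            n = rng.uniform(0.8, 2.2)
            d = float(rng.choice([50.0, 200.0, 400.0]))
            t_star = solve_swim_time(d, PhysioParams(mapv, a, e), SwimParams(k, n), MALE, C)

            def g(t):
                return supply(t, mapv, a, e) - k * (d / t) ** (n + 1)

            coarse = np.arange(d / 4.0, d / 0.5, 0.01)
            sign = np.signbit(g(coarse))
            idx = int(np.flatnonzero(sign[1:] != sign[:-1])[0])
            fine = np.arange(coarse[idx] - 0.01, coarse[idx + 1] + 0.01, 1e-4)
            fsign = np.signbit(g(fine))
            j = int(np.flatnonzero(fsign[1:] != fsign[:-1])[0])
            assert abs(t_star - fine[j]) <= 2e-4
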