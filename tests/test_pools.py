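"""Unit and property tests for the four-pool daily carbon-balance model."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import soilcarbon as sc
from soilcarbon.errors import (
    InputError,
    NoSteadyStateError,
    ParameterError,
    StateError,
)

densities = st.floats(0.0, 100.0, allow_nan=False)


class TestHalfLifeArithmetic:
    @pytest.mark.parametrize(
        "rate, years, digits",
        [
            (2.5e-4, 7.6, 1),  # light pool
            (2.6e-5, 73.0, 0),  # heavy pool, calibrated
            (1.8e-5, 105.4, 1),  # heavy pool, pre-calibration
        ],
    )
    def test_published_rate_half_life_pairs(self, rate, years, digits):
        assert round(sc.half_life_years(rate), digits) == years

    @pytest.mark.parametrize("t_half", [0.1, 2.3, 7.6, 105.4])
    def test_round_trip(self, t_half):
        assert sc.half_life_years(sc.rate_from_half_life(t_half)) == pytest.approx(
            t_half, rel=1e-12
        )

    def test_residue_pool_rates(self):
        assert sc.rate_from_half_life(0.1) == pytest.approx(
            math.log(2) / (0.1 * 365.25), rel=1e-12
        )
        assert sc.rate_from_half_life(2.3) == pytest.approx(8.25e-4, rel=1e-3)

    @pytest.mark.parametrize("bad", [0.0, -1.0, float("nan")])
    def test_domain_errors(self, bad):
        with pytest.raises(ParameterError):
            sc.half_life_years(bad)
        with pytest.raises(ParameterError):
            sc.rate_from_half_life(bad)


class TestStateAndParams:
    def test_total_is_pool_sum(self):
        s = sc.PoolState(1.0, 2.0, 3.0, 4.0)
        assert s.total() == 10.0

    def test_negative_pool_rejected(self):
        with pytest.raises(StateError):
            sc.PoolState(labile=-0.1)

    def test_nan_pool_rejected(self):
        with pytest.raises(StateError):
            sc.PoolState(light=float("nan"))

    def test_parameter_set_variants(self):
        mod, orig = sc.DecompositionParams.modified(), sc.DecompositionParams.original()
        assert round(sc.half_life_years(mod.k_heavy)) == 73
        assert round(sc.half_life_years(orig.k_heavy), 1) == 105.4
        assert mod.f_light_heavy == 0.3 and orig.f_light_heavy == 0.45
        assert mod.k_light == orig.k_light == 2.5e-4

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ParameterError):
            sc.DecompositionParams(f_light_heavy=1.2)
        with pytest.raises(ParameterError):
            sc.DecompositionParams(k_light=-1e-4)


class TestStepDay:
    def test_empty_system_stays_empty(self, params):
        state, flux = sc.step_day(sc.PoolState(), params)
        assert state.total() == 0.0 and flux.co2_c == 0.0

    def test_frozen_kinetics_only_adds_inputs(self, params):
        start = sc.PoolState(1.0, 2.0, 3.0, 4.0)
        state, flux = sc.step_day(start, params, f_env=0.0, input_labile=0.5)
        assert state.labile == pytest.approx(1.5)
        assert (state.resistant, state.light, state.heavy) == (2.0, 3.0, 4.0)
        assert flux.co2_c == 0.0

    def test_light_pool_decomposition_routing(self, params):
        # hand evaluation: D = 100·(1−exp(−K_LC)); heavy gains 0.3·D, CO₂ is 0.7·D
        state, flux = sc.step_day(sc.PoolState(light=100.0), params, f_env=1.0)
        d = 100.0 * (1.0 - math.exp(-2.5e-4))
        assert state.heavy == pytest.approx(0.3 * d, rel=1e-12)
        assert flux.co2_c == pytest.approx(0.7 * d, rel=1e-12)
        assert state.light == pytest.approx(100.0 - d, rel=1e-12)

    def test_negative_input_rejected(self, params):
        with pytest.raises(InputError):
            sc.step_day(sc.PoolState(), params, input_labile=-1.0)

    def test_negative_f_env_rejected(self, params):
        with pytest.raises(ParameterError):
            sc.step_day(sc.PoolState(), params, f_env=-0.5)

    @given(
        labile=densities,
        resistant=densities,
        light=densities,
        heavy=densities,
        f_env=st.floats(0.0, 3.0),
        u_l=st.floats(0.0, 1.0),
        u_r=st.floats(0.0, 1.0),
    )
    def test_mass_balance_and_nonnegativity(
        self, labile, resistant, light, heavy, f_env, u_l, u_r
    ):
        params = sc.DecompositionParams.modified()
        start = sc.PoolState(labile, resistant, light, heavy)
        state, flux = sc.step_day(start, params, f_env, u_l, u_r)
        delta = state.total() - start.total()
        assert delta == pytest.approx(flux.input_c - flux.co2_c, abs=1e-9 * max(1.0, start.total()))
        assert min(state.labile, state.resistant, state.light, state.heavy) >= 0.0


class TestTrajectory:
    def test_zero_days_returns_initial_state(self, params):
        start = sc.PoolState(1.0, 1.0, 10.0, 20.0)
        tr = sc.run_trajectory(start, params, np.ones(0), np.zeros((0, 2)))
        assert tr.final_state == start
        assert tr.annual_soc.tolist() == [start.total()]

    def test_cumulative_mass_balance(self, params, rng):
        f = rng.uniform(0.3, 1.8, 3650)
        u = rng.uniform(0.0, 0.01, (3650, 2))
        start = sc.PoolState(0.5, 1.0, 8.0, 25.0)
        tr = sc.run_trajectory(start, params, f, u)
        lhs = tr.total_input - tr.total_co2
        rhs = tr.final_state.total() - start.total()
        assert lhs == pytest.approx(rhs, rel=1e-10, abs=1e-10)

    def test_matrix_power_oracle(self, random_params_factory, rng):
        """The trajectory equals the closed form of the affine daily map."""
        for _ in range(5):
            p = random_params_factory(rng)
            f = float(rng.uniform(0.2, 2.0))
            u = np.array([rng.uniform(0, 0.01), rng.uniform(0, 0.01)])
            x0 = rng.uniform(0.0, 30.0, 4)
            n = 1500
            A = p.transfer_matrix(f)
            An = np.linalg.matrix_power(A, n)
            geom = np.linalg.solve(np.eye(4) - A, A - An @ A)  # Σ_{k=1..n} A^k
            expected = An @ x0 + geom @ np.array([u[0], u[1], 0.0, 0.0])
            tr = sc.run_trajectory(
                sc.PoolState.from_array(x0), p, np.full(n, f), np.tile(u, (n, 1))
            )
            np.testing.assert_allclose(
                tr.final_state.as_array(), expected, rtol=1e-8, atol=1e-12
            )

    def test_pure_decay_is_strictly_decreasing(self, params):
        start = sc.PoolState(1.0, 2.0, 10.0, 20.0)
        tr = sc.run_trajectory(start, params, np.ones(5 * 365), np.zeros((5 * 365, 2)))
        assert np.all(np.diff(tr.annual_soc) < 0)

    def test_constant_forcing_reaches_fixed_point(self, params):
        """Long runs converge to the steady state of the daily map."""
        u_l, u_r = 0.002, 0.0015
        ss = sc.steady_state(params, 1.0, u_l, u_r)
        n = 40000
        u = np.tile([u_l, u_r], (n, 1))
        tr = sc.run_trajectory(sc.PoolState(), params, np.ones(n), u)
        # pools equilibrate at their own rates: residue pools essentially
        # exactly, light to ~exp(-K_LC·n), heavy (73 y half-life) from below
        final = tr.final_state.as_array()
        target = ss.as_array()
        assert np.all(np.abs(final[:2] - target[:2]) / target[:2] < 1e-9)
        assert abs(final[2] - target[2]) / target[2] < 1e-3
        assert 0.5 * target[3] < final[3] < target[3]

    def test_mismatched_series_rejected(self, params):
        with pytest.raises(InputError):
            sc.run_trajectory(sc.PoolState(), params, np.ones(10), np.zeros((5, 2)))


class TestEnvModifier:
    def test_neutral_mode_is_identically_one(self):
        cfg = sc.EnvModifierConfig(mode="neutral")
        assert sc.env_modifier(35.0, 0.1, cfg) == 1.0
        assert np.all(sc.env_modifier(np.array([0.0, 40.0]), 0.0, cfg) == 1.0)

    def test_reference_conditions_normalise_to_one(self):
        cfg = sc.EnvModifierConfig(mode="climate", q10=2.0, t_ref_c=25.0)
        assert sc.env_modifier(25.0, 1.0, cfg) == pytest.approx(1.0)

    def test_q10_doubles_per_ten_degrees(self):
        cfg = sc.EnvModifierConfig(mode="climate", q10=2.0, t_ref_c=25.0)
        assert sc.env_modifier(35.0, 1.0, cfg) == pytest.approx(2.0)

    def test_monotone_in_temperature_and_moisture(self):
        cfg = sc.EnvModifierConfig(mode="climate")
        temps = np.linspace(-5, 45, 11)
        vals = sc.env_modifier(temps, 1.0, cfg)
        assert np.all(np.diff(vals) > 0)
        moist = sc.env_modifier(25.0, np.linspace(0, 1, 11), cfg)
        assert np.all(np.diff(moist) >= 0)
        assert np.all(np.asarray(vals) >= 0)


class TestSpinUp:
    def test_zero_years_gives_quarter_three_quarter_split(self, params):
        state = sc.spin_up(28.0, params, np.ones(365), np.zeros((365, 2)), n_years=0)
        assert state.light == pytest.approx(7.0)
        assert state.heavy == pytest.approx(21.0)
        assert (state.labile, state.resistant) == (0.0, 0.0)

    @pytest.mark.parametrize("n_years", [1, 17, 100])
    def test_total_is_preserved_exactly(self, params, n_years):
        u = np.full((365, 2), 1e-3)
        state = sc.spin_up(30.0, params, np.ones(365), u, n_years=n_years)
        assert state.total() == pytest.approx(30.0, rel=1e-12)

    def test_zero_input_shifts_proportion_toward_heavy(self, params):
        state = sc.spin_up(30.0, params, np.ones(365), np.zeros((365, 2)), n_years=50)
        assert state.heavy / state.total() > 0.75
        assert state.light / state.total() < 0.25

    def test_nonpositive_total_rejected(self, params):
        with pytest.raises(InputError):
            sc.spin_up(0.0, params, np.ones(365), np.zeros((365, 2)))


class TestSteadyState:
    def test_zero_input_fixed_point_is_empty(self, params):
        assert sc.steady_state(params, 1.0, 0.0, 0.0).total() == 0.0

    def test_is_fixed_point_of_step_day(self, params):
        ss = sc.steady_state(params, 1.0, 0.003, 0.002)
        after, _ = sc.step_day(ss, params, 1.0, 0.003, 0.002)
        np.testing.assert_allclose(
            after.as_array(), ss.as_array(), rtol=1e-10, atol=1e-12
        )

    def test_linearity_in_inputs(self, params):
        one = sc.steady_state(params, 1.0, 0.002, 0.001)
        two = sc.steady_state(params, 1.0, 0.004, 0.002)
        np.testing.assert_allclose(two.as_array(), 2.0 * one.as_array(), rtol=1e-10)

    def test_no_steady_state_when_frozen_with_input(self, params):
        with pytest.raises(NoSteadyStateError):
            sc.steady_state(params, 0.0, 0.01, 0.0)


class TestRequiredExtraInput:
    def test_steady_baseline_needs_nothing(self, params):
        u_daily = 0.003
        ss = sc.steady_state(params, 1.0, 0.59 * u_daily, 0.41 * u_daily)
        u = np.tile([0.59 * u_daily, 0.41 * u_daily], (365, 1))
        extra = sc.required_extra_input(ss, params, np.ones(365), u, horizon_years=5)
        assert extra == 0.0

    def test_returned_amount_closes_the_gap(self, params):
        start = sc.PoolState(0.0, 0.0, 8.0, 24.0)
        u = np.tile([0.001, 0.0008], (365, 1))
        horizon = 10
        extra = sc.required_extra_input(start, params, np.ones(365), u, horizon)
        daily = extra / 365.0
        u2 = u + np.array([0.59 * daily, 0.41 * daily])
        n = horizon * 365
        tr = sc.run_trajectory(start, params, np.ones(n), np.tile(u2, (n // 365, 1)))
        assert abs(tr.final_state.total() - start.total()) < 0.05

    def test_monotone_in_starting_stock(self, params):
        u = np.tile([0.001, 0.0008], (365, 1))
        lo = sc.required_extra_input(
            sc.PoolState(0, 0, 6.0, 18.0), params, np.ones(365), u, 10
        )
        hi = sc.required_extra_input(
            sc.PoolState(0, 0, 9.0, 27.0), params, np.ones(365), u, 10
        )
        assert hi > lo > 0

    def test_bad_horizon_rejected(self, params):
        with pytest.raises(InputError):
            sc.required_extra_input(
                sc.PoolState(0, 0, 8, 24), params, np.ones(365), np.zeros((365, 2)), 0
            )
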