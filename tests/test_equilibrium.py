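import math

import numpy as np
import pytest
from scipy.integrate import quad

from mbwater import ModelParameters, ThermoState
from mbwater.equilibrium import (
    _d1,
    _log_psi_from_weights,
    _populations_from_weights,
    StateWeights,
    dlogpsi_dp_analytic,
    dlogpsi_dt_analytic,
    entropy_analytic,
    gibbs_per_molecule,
    hb_angular_integral,
    hexagon_partition,
    log_psi,
    mean_spring_energy,
    populations,
    state_weights,
    thermo_derivatives,
    volume_analytic,
)
from mbwater.oracle import quadrature_oracle


class TestAngularIntegral:
    def test_no_spring_gives_unity(self, state):
        assert hb_angular_integral(state, ModelParameters(k_s=0.0)) == 1.0

    def test_collapses_at_zero_temperature(self, params):
        # the orientational factor shrinks like sqrt(T) as the well narrows
        cold, colder = ThermoState(t_star=1e-4), ThermoState(t_star=1e-8)
        i_cold, i_colder = (hb_angular_integral(s, params) for s in (cold, colder))
        assert i_cold < 5e-3
        assert i_colder == pytest.approx(i_cold * 1e-2, rel=1e-6)

    def test_bounded_in_unit_interval(self, params, random_states):
        for st in random_states:
            assert 0.0 < hb_angular_integral(st, params) <= 1.0

    def test_matches_trapezoid_oracle(self, params, state):
        tm = params.theta_max
        oracle = quadrature_oracle(
            lambda th: math.exp(-state.beta * params.k_s * th * th), -tm, tm, 100_000
        ) / (2 * tm)
        assert hb_angular_integral(state, params) == pytest.approx(oracle, abs=1e-8)

    def test_matches_adaptive_quadrature(self, params, state):
        tm = params.theta_max
        val, _ = quad(lambda th: math.exp(-state.beta * params.k_s * th * th), -tm, tm)
        assert hb_angular_integral(state, params) == pytest.approx(val / (2 * tm), abs=1e-10)


class TestMeanSpringEnergy:
    def test_matches_boltzmann_weighted_quadrature(self, params, state):
        tm = params.theta_max
        w = lambda th: math.exp(-state.beta * params.k_s * th * th)
        num = quadrature_oracle(lambda th: params.k_s * th * th * w(th), -tm, tm, 100_000)
        den = quadrature_oracle(w, -tm, tm, 100_000)
        assert mean_spring_energy(state, params) == pytest.approx(num / den, abs=1e-8)

    def test_equipartition_at_low_temperature(self, params):
        cold = ThermoState(t_star=0.01)
        assert mean_spring_energy(cold, params) == pytest.approx(cold.t_star / 2, rel=1e-6)

    def test_uniform_average_without_spring_weighting(self, params):
        hot = ThermoState(t_star=1e4)
        expected = params.k_s * params.theta_max ** 2 / 3
        assert mean_spring_energy(hot, params) == pytest.approx(expected, rel=1e-3)


class TestStateWeights:
    def test_no_cooperativity_energy_gives_unit_factor(self, state):
        w = state_weights(state, ModelParameters(eps_c=0.0))
        assert w.delta_coop == 1.0

    def test_cage_weight_equals_hb_weight_when_volumes_match(self, state):
        w = state_weights(state, ModelParameters(v_c=0.8, v_hb=0.8))
        assert w.log_c == w.log_hb  # bitwise, in log space

    def test_all_weights_unity_without_interactions(self):
        p = ModelParameters(eps_hb=0.0, eps_lj=0.0, eps_c=0.0, k_s=0.0)
        w = state_weights(ThermoState(t_star=0.3, p_star=0.0), p)
        assert (w.delta_hb, w.delta_lj, w.delta_0, w.delta_c, w.delta_coop) == (
            1.0, 1.0, 1.0, 1.0, 1.0)

    def test_weights_survive_deep_cold(self, params):
        # beta = 50: exponents handled in log space without overflow
        w = state_weights(ThermoState(t_star=0.02, p_star=0.5), params)
        assert math.isfinite(w.log_hb) and math.isfinite(w.log_c)


def _uniform_weights(log_delta: float = 0.0) -> StateWeights:
    return StateWeights(log_hb=log_delta, log_lj=log_delta, log_0=log_delta,
                        log_c=log_delta, log_coop=0.0)


class TestHexagonPartition:
    def test_uniform_weights_closed_form(self):
        """All weights Delta and unit cooperativity: the removed all-HB
        term is exactly replaced by the cage channel, Psi = (3 Delta)**6."""
        for log_delta in (0.0, 0.7, -1.2):
            lp = _log_psi_from_weights(_uniform_weights(log_delta))
            assert lp == pytest.approx(6 * (math.log(3) + log_delta), rel=1e-12)

    def test_cage_channel_vanishes_without_cooperativity_factor(self):
        w = StateWeights(log_hb=0.3, log_lj=0.1, log_0=0.0, log_c=0.3, log_coop=-745.0)
        s = math.exp(0.3) + math.exp(0.1) + 1.0
        expected = math.log(s ** 6 - math.exp(0.3) ** 6)
        assert _log_psi_from_weights(w) == pytest.approx(expected, rel=1e-12)

    def test_monotone_increasing_in_each_weight(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            logs = rng.normal(0.0, 1.0, size=4)
            w = StateWeights(*logs, log_coop=-0.1)
            base = _log_psi_from_weights(w)
            for field in ("log_hb", "log_lj", "log_0", "log_c"):
                bumped = {f: getattr(w, f) for f in
                          ("log_hb", "log_lj", "log_0", "log_c", "log_coop")}
                bumped[field] += 1e-6
                assert _log_psi_from_weights(StateWeights(**bumped)) > base

    def test_matches_direct_arithmetic_at_state_point(self, params, state):
        w = state_weights(state, params)
        psi = ((w.delta_hb + w.delta_lj + w.delta_0) ** 6
               - w.delta_hb ** 6 + (w.delta_coop * w.delta_c) ** 6)
        assert hexagon_partition(state, params) == pytest.approx(math.log(psi), rel=1e-12)


class TestPopulations:
    def test_uniform_weights_closed_form(self):
        f = _populations_from_weights(_uniform_weights())
        assert f[0] == pytest.approx(242 / 729, rel=1e-12)
        assert f[1] == pytest.approx(243 / 729, rel=1e-12)
        assert f[2] == pytest.approx(243 / 729, rel=1e-12)
        assert f[3] == pytest.approx(1 / 729, rel=1e-12)

    def test_hydrogen_bond_dominated_limit(self):
        """With the LJ, open and cage channels suppressed, the surviving
        configurations have five HB bonds plus one defect (the all-HB
        hexagon belongs to the cage channel), so f_hb -> 5/6."""
        w = StateWeights(log_hb=0.0, log_lj=-12.0, log_0=-12.0,
                         log_c=0.0, log_coop=-500.0)
        f = _populations_from_weights(w)
        assert f[0] == pytest.approx(5 / 6, rel=1e-4)
        assert f[1] + f[2] == pytest.approx(1 / 6, rel=1e-4)
        assert f[3] == 0.0

    def test_pure_cage_limit(self):
        """Suppressing LJ and open bonds while keeping the cage channel
        finite leaves only complete hexagonal cages."""
        w = StateWeights(log_hb=0.0, log_lj=-200.0, log_0=-200.0,
                         log_c=0.0, log_coop=0.0)
        f = _populations_from_weights(w)
        assert f[3] == pytest.approx(1.0, rel=1e-9)

    def test_infinite_temperature_approaches_uniform_case(self, params):
        f = populations(ThermoState(t_star=1e6, p_star=0.0), params)
        assert f[0] == pytest.approx(242 / 729, abs=1e-4)
        assert f[3] == pytest.approx(1 / 729, abs=1e-4)

    def test_normalised_across_liquid_range(self, params, random_states):
        for st in random_states:
            assert sum(populations(st, params)) == pytest.approx(1.0, abs=1e-12)


class TestThermodynamics:
    def test_gibbs_proportional_to_log_partition(self, params, state):
        g = gibbs_per_molecule(state, params)
        assert g == pytest.approx(-(state.t_star / 6) * hexagon_partition(state, params))

    def test_gibbs_decreases_with_stronger_bonding(self, params, state):
        g0 = gibbs_per_molecule(state, params)
        for stronger in ({"eps_hb": 1.05}, {"eps_lj": 0.15}, {"eps_c": 0.0}):
            # eps_c enters as a penalty on the cage channel, so removing it
            # also lowers g
            g1 = gibbs_per_molecule(state, params.evolve(**stronger))
            assert g1 < g0

    def test_numeric_matches_analytic_first_derivatives(self, params, random_states):
        for st in random_states:
            num_p = _d1(lambda p: log_psi(st.t_star, p, params), st.p_star)
            num_t = _d1(lambda t: log_psi(t, st.p_star, params), st.t_star)
            ana_p = dlogpsi_dp_analytic(st, params)
            ana_t = dlogpsi_dt_analytic(st, params)
            assert num_p == pytest.approx(ana_p, rel=1e-6)
            assert num_t == pytest.approx(ana_t, rel=1e-6)

    def test_volume_is_population_weighted_mixture(self, params, random_states):
        for st in random_states:
            f = populations(st, params)
            vmix = (f[0] * params.v_hb + f[1] * params.v_lj
                    + f[2] * params.v_0 + f[3] * params.v_c)
            assert thermo_derivatives(st, params).v == pytest.approx(vmix, rel=1e-8)

    def test_thermodynamic_identities(self, params, random_states):
        for st in random_states:
            eq = thermo_derivatives(st, params)
            assert eq.g == pytest.approx(eq.h - st.t_star * eq.s, abs=1e-8)
            assert eq.s == pytest.approx(entropy_analytic(st, params), rel=1e-6)
            assert eq.cp - eq.cv == pytest.approx(
                st.t_star * eq.v * eq.alpha_p ** 2 / eq.kappa_t, rel=1e-5)
            assert eq.cp >= eq.cv
            assert eq.kappa_t > 0 and eq.v > 0
            assert eq.rho == pytest.approx(1.0 / eq.v)

    def test_heat_capacity_positive_on_liquid_grid(self, params):
        """g(T) concave: cp >= 0 across the liquid range."""
        for t in np.linspace(0.15, 0.38, 6):
            for p in (0.05, 0.5, 1.0):
                eq = thermo_derivatives(ThermoState(float(t), p), params)
                assert eq.cp >= 0.0

    def test_volume_analytic_consistent(self, params, state):
        assert volume_analytic(state, params) == pytest.approx(
            thermo_derivatives(state, params).v, rel=1e-8)
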