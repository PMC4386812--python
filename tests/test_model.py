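"""Model parameter tables, steady-state analysis and small-signal properties."""

import numpy as np
import pytest

from laminaris import (
    ModelSpec,
    NodeParams,
    SomaParams,
    SpikeGenerator,
    find_holding_current,
    impedance_magnitude,
    input_resistance,
    membrane_time_constant,
    resting_potential,
    spike_current,
    steady_state_residual,
)
from laminaris.model import node_steady_state


class TestDefaults:
    """Default instances carry the published membrane/threshold parameters."""

    def test_shared_soma(self, one_comp_active, two_comp_active):
        for spec in (one_comp_active, two_comp_active):
            s = spec.soma
            assert (s.c_soma, s.g_leak, s.g_klva) == (24.0, 48.0, 192.0)
            assert (s.e_leak, s.e_k, s.e_syn) == (-60.0, -75.0, 0.0)

    def test_passive_soma(self, one_comp_passive):
        s = one_comp_passive.soma
        assert (s.c_soma, s.g_leak, s.g_klva) == (24.0, 240.0, 0.0)

    def test_node(self, two_comp_active):
        n = two_comp_active.node
        assert (n.c_node, n.g_leak, n.g_axon) == (0.2, 2.0, 117.8)

    @pytest.mark.parametrize(
        "variant, a1, a2, v_theta",
        [
            ("two_comp_active_if", 4000.0, 3000.0, -56.7),
            ("one_comp_active_if", 3500.0, 3000.0, -58.3),
            ("one_comp_passive_if", 4000.0, 4000.0, -58.6),
        ],
    )
    def test_generator(self, variant, a1, a2, v_theta):
        g = ModelSpec.default(variant).gen
        assert (g.a1, g.a2, g.v_theta) == (a1, a2, v_theta)
        assert (g.i_const, g.tau1, g.tau2, g.t_ref) == (200.0, 0.02, 0.20, 0.9)

    def test_variant_constraints(self):
        with pytest.raises(ValueError):
            ModelSpec("one_comp_active_if", SomaParams(), NodeParams(), SpikeGenerator())
        with pytest.raises(ValueError):
            ModelSpec("non_spiking", SomaParams(), None, SpikeGenerator())
        with pytest.raises(ValueError):
            ModelSpec("two_comp_active_if", SomaParams(), None, SpikeGenerator())
        with pytest.raises(ValueError):  # passive variant must drop K_LVA
            ModelSpec("one_comp_passive_if", SomaParams(g_leak=240.0), None,
                      SpikeGenerator())


class TestSpikeCurrent:
    def test_zero_before_onset(self, one_comp_active):
        assert spike_current(-0.1, one_comp_active.gen) == 0.0

    @pytest.mark.parametrize(
        "variant, peak",
        [("one_comp_active_if", 6500.0), ("two_comp_active_if", 7000.0),
         ("one_comp_passive_if", 8000.0)],
    )
    def test_onset_amplitude(self, variant, peak):
        assert spike_current(0.0, ModelSpec.default(variant).gen) == peak

    def test_double_exponential_form(self, one_comp_active):
        gen = one_comp_active.gen
        t = np.linspace(0.0, 1.0, 11)
        expected = gen.a1 * np.exp(-t / gen.tau1) + gen.a2 * np.exp(-t / gen.tau2)
        np.testing.assert_allclose(spike_current(t, gen), expected, rtol=1e-12)


class TestSteadyState:
    def test_passive_equilibrium_closed_form(self, one_comp_passive):
        # E_L + I_const/g_leak = -60 + 200/240
        v_eq = -60.0 + 200.0 / 240.0
        assert steady_state_residual(v_eq, one_comp_passive) == pytest.approx(0.0, abs=1e-9)
        assert resting_potential(one_comp_passive) == pytest.approx(v_eq, abs=1e-6)

    def test_active_residual_at_minus_60(self, one_comp_active):
        # 192 * dinf(-60) * (E_K - V) + I_const = 192*0.5405*(-15) + 200
        expected = 192.0 * (0.20 / 0.37) * (-15.0) + 200.0
        assert steady_state_residual(-60.0, one_comp_active) == pytest.approx(
            expected, abs=1e-9
        )

    def test_node_steady_state_linear_solve(self, two_comp_active):
        # (g_ln*E_L + g_ax*V_s + I_const) / (g_ln + g_ax) at V_s = -60
        expected = (2.0 * -60.0 + 117.8 * -60.0 + 200.0) / 119.8
        assert node_steady_state(-60.0, two_comp_active) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "variant, i_base",
        [("one_comp_passive_if", -200.0), ("one_comp_active_if", 1356.76),
         ("two_comp_active_if", 1360.10)],
    )
    def test_holding_current_at_minus_60(self, variant, i_base):
        spec = ModelSpec.default(variant)
        assert find_holding_current(spec, -60.0) == pytest.approx(i_base, abs=0.01)
        # the returned current does hold the potential
        assert steady_state_residual(-60.0, spec, i_base) == pytest.approx(0.0, abs=0.02)

    def test_resting_potentials_ordered(self, one_comp_active, two_comp_active,
                                        non_spiking):
        # active variants rest between E_K and E_L; the IF models sit above
        # the non-spiking one because of the depolarizing constant current
        v1 = resting_potential(one_comp_active)
        v2 = resting_potential(two_comp_active)
        v0 = resting_potential(non_spiking)
        assert -75.0 < v0 < v2 < -60.0
        assert v1 == pytest.approx(-66.9, abs=0.1)
        assert steady_state_residual(v0, non_spiking) == pytest.approx(0.0, abs=1e-6)

    def test_holding_current_range_check(self, one_comp_active):
        with pytest.raises(ValueError):
            find_holding_current(one_comp_active, -30.0)


class TestSmallSignal:
    def test_passive_resistance_is_inverse_leak(self, one_comp_passive):
        for v_hold in (-65.0, -61.0, -55.0):
            assert input_resistance(one_comp_passive, v_hold) == pytest.approx(
                1e3 / 240.0, rel=1e-6
            )

    def test_active_slope_resistance_at_minus_61(self, one_comp_active):
        r = input_resistance(one_comp_active, -61.0)
        assert r == pytest.approx(4.4, abs=0.1)
        tau = membrane_time_constant(one_comp_active, -61.0)
        assert tau == pytest.approx(0.107, abs=0.01)

    def test_passive_impedance_closed_form(self, one_comp_passive):
        f = np.array([10.0, 1e3, 1e4])
        g, c = 240.0, 24.0
        expected = 1e3 / np.abs(g + 1j * 2 * np.pi * f * 1e-3 * c)
        np.testing.assert_allclose(
            impedance_magnitude(one_comp_passive, -61.0, f), expected, rtol=1e-12
        )

    def test_zero_frequency_matches_slope_resistance(self, one_comp_active):
        z0 = impedance_magnitude(one_comp_active, -61.0, 0.0)
        assert z0 == pytest.approx(input_resistance(one_comp_active, -61.0), rel=1e-4)

    def test_klva_lowers_low_frequency_impedance(self, one_comp_active):
        z_rc = impedance_magnitude(one_comp_active, -61.0, 50.0, include_klva=False)
        z_full = impedance_magnitude(one_comp_active, -61.0, 50.0)
        assert z_full < z_rc

    def test_axon_lowers_somatic_impedance(self, two_comp_active):
        z_no_axon = impedance_magnitude(two_comp_active, -61.0, 50.0, include_axon=False)
        z_full = impedance_magnitude(two_comp_active, -61.0, 50.0)
        assert z_full < z_no_axon
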