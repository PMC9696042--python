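"""Mass-action engine: source terms, rate laws, integrator accuracy."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import radiokin as rk
from radiokin.core import CROSSLINK_SPECIES, assemble_rhs


def simple_network(reactions, species, g=None):
    net = rk.ReactionNetwork(g_yield=rk.GYield(g or {}))
    for name, c0 in species.items():
        net.add_species(rk.Species(name, c0))
    for lhs, rhs, k in reactions:
        net.react(lhs, rhs, k)
    return net


class TestDepositDose:
    def test_primary_increments_are_g_times_dose(self):
        g = rk.GYield()
        state = rk.deposit_dose({"OH": 0.0, "e_aq": 0.0, "H": 0.0, "X": 1.0}, 1.0, g)
        assert state["OH"] == pytest.approx(2.87e-7, rel=1e-12)
        assert state["e_aq"] == pytest.approx(2.7e-7, rel=1e-12)
        assert state["H"] == pytest.approx(5.5e-8, rel=1e-12)
        assert state["X"] == 1.0  # non-primaries untouched

    def test_zero_dose_is_identity(self):
        before = {"OH": 1e-6}
        assert rk.deposit_dose(before, 0.0, rk.GYield()) == before

    def test_scales_linearly_with_dose(self):
        state = rk.deposit_dose({"OH": 0.0}, 4.5, rk.GYield())
        assert state["OH"] == pytest.approx(1.2915e-6, rel=1e-12)

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError):
            rk.deposit_dose({}, -1.0, rk.GYield())

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(d1=st.floats(0, 100), d2=st.floats(0, 100))
    def test_dose_additivity(self, d1, d2):
        g = rk.GYield()
        split = rk.deposit_dose(rk.deposit_dose({"OH": 0.0}, d1, g), d2, g)
        once = rk.deposit_dose({"OH": 0.0}, d1 + d2, g)
        assert split["OH"] == pytest.approx(once["OH"], rel=1e-9, abs=1e-300)


class TestAssembleRhs:
    def test_first_order_rate(self):
        net = simple_network([("A", "B", 1.0)], {"A": 1.0, "B": 0.0})
        rhs, _ = assemble_rhs(net)
        dy = rhs(0.0, np.array([1.0, 0.0]))
        assert dy[0] == pytest.approx(-1.0)
        assert dy[1] == pytest.approx(1.0)

    def test_dimerization_consumes_two(self):
        net = simple_network([("2 A", "B", 3.0)], {"A": 2.0, "B": 0.0})
        rhs, _ = assemble_rhs(net)
        dy = rhs(0.0, np.array([2.0, 0.0]))
        assert dy[0] == pytest.approx(-2 * 3.0 * 4.0)  # -2k[A]^2
        assert dy[1] == pytest.approx(3.0 * 4.0)

    def test_bimolecular_rate_thiocyanate_constants(self):
        net = simple_network(
            [("SCN- + OH", "SCN", 2.8e10)], {"SCN-": 1e-3, "OH": 1e-6, "SCN": 0.0}
        )
        rhs, _ = assemble_rhs(net)
        dy = rhs(0.0, np.array([1e-3, 1e-6, 0.0]))
        assert dy[2] == pytest.approx(28.0)  # k[SCN-][OH] = 2.8e10 * 1e-9

    def test_undeclared_species_rejected(self):
        net = rk.ReactionNetwork()
        net.add_species(rk.Species("A"))
        with pytest.raises(rk.NetworkError):
            net.react("A + B", "C", 1.0)

    def test_order_three_rejected(self):
        with pytest.raises(rk.NetworkError):
            rk.Reaction([("A", 3)], [("B", 1)], 1.0)

    def test_jacobian_matches_finite_differences(self):
        net = simple_network(
            [("A + B", "C", 2.0), ("2 A", "B", 0.5), ("C", "A", 1.5)],
            {"A": 0.3, "B": 0.7, "C": 0.2},
        )
        rhs, jac = assemble_rhs(net)
        y = np.array([0.3, 0.7, 0.2])
        J = jac(0.0, y)
        eps = 1e-7
        for j in range(3):
            dy = np.zeros(3)
            dy[j] = eps
            fd = (rhs(0.0, y + dy) - rhs(0.0, y - dy)) / (2 * eps)
            np.testing.assert_allclose(J[:, j], fd, rtol=1e-6, atol=1e-9)


class TestIntegrate:
    def test_first_order_decay_matches_closed_form(self):
        k = 2.0
        net = simple_network([("A", "B", k)], {"A": 1.0, "B": 0.0})
        tc = rk.integrate(net, None, 3.0, output_grid=np.linspace(0, 3, 50))
        expected = np.exp(-k * tc.times)
        np.testing.assert_allclose(tc["A"], expected, rtol=1e-6)

    def test_equal_conc_second_order_matches_closed_form(self):
        # A + B -> C with [A]0 = [B]0: [A](t) = 1/(1/[A]0 + k t)
        k, c0 = 5.0, 0.4
        net = simple_network([("A + B", "C", k)], {"A": c0, "B": c0, "C": 0.0})
        tc = rk.integrate(net, None, 10.0, output_grid=np.linspace(0, 10, 50))
        expected = 1.0 / (1.0 / c0 + k * tc.times)
        np.testing.assert_allclose(tc["A"], expected, rtol=1e-6)

    def test_source_only_network_accumulates_g_r_t(self):
        # no reactions: [primary](t) = G * r * t exactly
        net = rk.ReactionNetwork()
        for name in ("OH", "e_aq", "H"):
            net.add_species(rk.Species(name, role="radiolytic_primary"))
        rate = 2.0  # Gy/s
        protocol = rk.IrradiationProtocol.continuous(
            dose_rate_gy_s=rate, total_dose_gy=rate * 100.0
        )
        tc = rk.integrate(net, protocol, 100.0, output_grid=np.linspace(0, 100, 11))
        np.testing.assert_allclose(
            tc["OH"], 0.287e-6 * rate * tc.times, rtol=1e-8, atol=1e-18
        )
        np.testing.assert_allclose(tc.cumulative_dose, rate * tc.times, rtol=1e-12)

    def test_continuous_source_stops_at_total_dose(self):
        net = rk.ReactionNetwork()
        net.add_species(rk.Species("OH", role="radiolytic_primary"))
        protocol = rk.IrradiationProtocol.continuous(
            dose_rate_gy_s=1.0, total_dose_gy=10.0
        )
        tc = rk.integrate(net, protocol, 20.0, output_grid=np.linspace(0, 20, 21))
        assert tc.final("OH") == pytest.approx(0.287e-6 * 10.0, rel=1e-7)
        assert tc.cumulative_dose[-1] == pytest.approx(10.0)

    def test_conservation_with_tag(self):
        net = simple_network(
            [("A + B", "C", 4.0), ("C", "A + B", 0.3)],
            {"A": 1e-3, "B": 2e-3, "C": 0.0},
        )
        net.tags["a_atoms"] = {"A": 1.0, "C": 1.0}
        tc = rk.integrate(net, None, 50.0, output_grid=np.linspace(0, 50, 20))
        total = tc.tag_total("a_atoms")
        np.testing.assert_allclose(total, total[0], rtol=1e-6)

    def test_pulsed_instantaneous_jump(self):
        net = rk.ReactionNetwork()
        net.add_species(rk.Species("OH", role="radiolytic_primary"))
        protocol = rk.IrradiationProtocol.single_pulse(4.5)
        tc = rk.integrate(net, protocol, 1e-6)
        assert tc["OH"][0] == pytest.approx(1.2915e-6, rel=1e-12)
        assert tc.final("OH") == pytest.approx(1.2915e-6, rel=1e-9)

    def test_rectangular_pulse_same_total_dose(self):
        net = rk.ReactionNetwork()
        net.add_species(rk.Species("OH", role="radiolytic_primary"))
        protocol = rk.IrradiationProtocol.single_pulse(
            4.5, pulse_width=10e-9, delivery="rectangular"
        )
        tc = rk.integrate(net, protocol, 1e-6)
        assert tc.final("OH") == pytest.approx(1.2915e-6, rel=1e-6)

    def test_outputs_never_negative(self, pulse_tc):
        assert pulse_tc.conc.min() >= 0.0

    def test_cumulative_dose_and_crosslink_non_decreasing(self, gamma_h5):
        tc, _ = gamma_h5
        assert np.all(np.diff(tc.cumulative_dose) >= 0)
        assert np.all(np.diff(tc.crosslink_conc) >= -1e-15)

    def test_invalid_arguments(self):
        net = simple_network([("A", "B", 1.0)], {"A": 1.0, "B": 0.0})
        with pytest.raises(ValueError):
            rk.integrate(net, None, -1.0)
        with pytest.raises(ValueError):
            rk.integrate(net, None, 1.0, rtol=-1e-8)


class TestProtocolAndUnits:
    def test_kgy_per_hour_conversion(self):
        assert rk.kgy_per_h_to_gy_per_s(1.0) == pytest.approx(0.277778, rel=1e-5)
        assert rk.kgy_per_h_to_gy_per_s(10.0) == pytest.approx(2.77778, rel=1e-5)

    def test_continuous_requires_positive_rate(self):
        with pytest.raises(ValueError):
            rk.IrradiationProtocol(mode="continuous", dose_rate=0.0, total_dose=5.0)

    def test_pulsed_cumulative_dose_steps(self):
        p = rk.IrradiationProtocol(
            mode="pulsed", dose_per_pulse=4.0, n_pulses=3, inter_pulse_interval=1.0
        )
        np.testing.assert_allclose(
            p.cumulative_dose(np.array([0.0, 0.5, 1.0, 2.5])), [4.0, 4.0, 8.0, 12.0]
        )
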