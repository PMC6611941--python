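import numpy as np
import pytest

from csfcircuit import (CircuitState, ModelParameters, ShuntSpec,
                        SimulationSettings, capillary_pressure,
                        conservation_residual, dc_steady_state, mean_icp,
                        simulate, state_derivative)
from csfcircuit.simulator import _branch_flows, diode_flags

from conftest import DC_ICP, DC_NORMAL_NODES

QUIET = dict(src_amp1=0.0, src_amp2=0.0)  # pulsatility off


class TestCapillaryPressure:
    def test_blocked_formation_with_equal_endpoints(self, params):
        # P_ic above the node pressure keeps the formation valve shut,
        # so the capillary node just sits between two equal endpoints.
        assert capillary_pressure(5.0, 5.0, 10.0, params) == pytest.approx(5.0)

    def test_hand_balance_with_equal_resistances(self, params):
        p = params.replace(R2=1.0, R3=1.0, Rf=1.0)
        # (3 - Pc)/1 = (Pc - 0)/1 + (Pc - 0)/1  =>  Pc = 1
        assert capillary_pressure(3.0, 0.0, 0.0, p) == pytest.approx(1.0)

    def test_normal_steady_state_ratio(self, params):
        # with Ro = 1 and Rf = 5 the intracranial node balance forces
        # P_c = 6 P_ic at steady state
        dc = dc_steady_state(params)
        assert dc.P_c == pytest.approx(6.0 * dc.P_ic, rel=1e-12)

    def test_valve_state_consistency_is_unique(self, params):
        # across a sweep of P_ic the returned pressure always satisfies the
        # balance with a valve flag consistent with itself
        for pic in np.linspace(-2000.0, 8000.0, 41):
            pc = capillary_pressure(7000.0, 2000.0, pic, params)
            f = 1.0 if pc > pic else 0.0
            lhs = (7000.0 - pc) / params.R2
            rhs = (pc - 2000.0) / params.R3 + f * (pc - pic) / params.Rf
            assert lhs == pytest.approx(rhs, abs=1e-9)


class TestDCSteadyState:
    @pytest.mark.parametrize(("ro", "rshunt"), sorted(DC_ICP, key=str))
    def test_icp_matches_symbolic_solve(self, params, ro, rshunt):
        dc = dc_steady_state(params.replace(Ro=ro), rshunt)
        assert dc.P_ic == pytest.approx(DC_ICP[(ro, rshunt)], abs=1e-3)

    def test_normal_node_pressures(self, params):
        dc = dc_steady_state(params)
        for name, expected in DC_NORMAL_NODES.items():
            assert getattr(dc, name) == pytest.approx(expected, abs=1e-3)

    def test_linearity_in_source_offset(self, params):
        base = dc_steady_state(params)
        doubled = dc_steady_state(params.replace(src_offset=32000.0))
        for name in ("P_a", "P_c", "P_v", "P_ic"):
            assert getattr(doubled, name) == pytest.approx(
                2.0 * getattr(base, name), rel=1e-12)

    def test_nonconducting_configuration_is_an_error(self, params):
        # a drainage terminal pressure above the whole network reverses the
        # absorption valve, invalidating the conducting-diode assumption
        with pytest.raises(RuntimeError, match="conducting"):
            dc_steady_state(params.replace(P_vs=1e6))

    def test_invalid_shunt_resistance_rejected(self, params):
        with pytest.raises(ValueError):
            dc_steady_state(params, rshunt=0.0)


class TestStateDerivative:
    def test_unforced_network_rests_at_reference(self, params):
        p = params.replace(**QUIET, src_offset=0.0)
        dy = state_derivative(0.0, np.zeros(3), p, ShuntSpec.absent())
        assert np.allclose(dy, 0.0, atol=1e-12)

    def test_dc_point_is_a_fixed_point(self, params):
        for ro, rshunt in [(1.0, None), (10.0, 1.25)]:
            p = params.replace(**QUIET, Ro=ro)
            dc = dc_steady_state(p, rshunt)
            sh = ShuntSpec.constant(rshunt) if rshunt else ShuntSpec.absent()
            dy = state_derivative(0.0, dc.state.as_array(), p, sh)
            assert np.allclose(dy, 0.0, atol=1e-6)

    def test_no_backflow_below_sinus_pressure(self, params):
        # intracranial pressure below the sinus reference shuts both
        # drainage valves: absorption and shunt flows are exactly zero
        p = params.replace(P_vs=2000.0)
        sh = ShuntSpec.constant(1.25)
        state = CircuitState.from_pressures(7000.0, 2500.0, 1000.0)
        pc = capillary_pressure(state.P_a, state.P_v, state.P_ic, p)
        q_f, q_o, q_sh = _branch_flows(0.0, pc, state.P_ic, p, sh)
        assert q_o == 0.0 and q_sh == 0.0 and q_f > 0.0
        assert diode_flags(pc, state.P_ic, p, sh) == (1, 0, 0)


class TestSimulate:
    def test_quiet_run_converges_to_dc_oracle(self, params):
        st = SimulationSettings(t_end=30.0)
        for ro, rshunt in [(1.0, None), (5.0, None), (10.0, None), (10.0, 1.11111)]:
            p = params.replace(**QUIET, Ro=ro)
            sh = ShuntSpec.constant(rshunt) if rshunt else ShuntSpec.absent()
            trace = simulate(p, sh, st)
            expected = dc_steady_state(p, rshunt).P_ic
            assert trace.P_ic[-1] == pytest.approx(expected, rel=1e-3)

    def test_dc_initialisation_starts_on_the_fixed_point(self, params):
        p = params.replace(**QUIET, Ro=10.0)
        trace = simulate(p, ShuntSpec.absent(),
                         SimulationSettings(t_end=5.0, init_mode="dc"))
        assert np.ptp(trace.P_ic) < 1e-4 * trace.P_ic[0]

    def test_volume_conservation_along_pulsatile_trace(self, params, normal_trace):
        res = conservation_residual(normal_trace, params, ShuntSpec.absent())
        peak_flow = np.max(np.abs(normal_trace.cbf))
        assert np.max(np.abs(res)) < 1e-6 * peak_flow

    def test_flows_are_unidirectional(self, params):
        p = params.replace(Ro=10.0)
        trace = simulate(p, ShuntSpec.constant(1.11111), SimulationSettings())
        assert trace.q_f.min() >= 0.0
        assert trace.q_o.min() >= 0.0
        assert trace.q_sh.min() >= 0.0

    def test_mean_icp_monotone_in_outflow_resistance(self, params):
        icps = [mean_icp(simulate(params.replace(Ro=ro), ShuntSpec.absent(),
                                  SimulationSettings()))
                for ro in (1.0, 5.0, 10.0)]
        assert icps[0] < icps[1] < icps[2]

    def test_mean_icp_monotone_in_shunt_resistance(self, params):
        p = params.replace(Ro=10.0)
        icps = [mean_icp(simulate(p, ShuntSpec.constant(r), SimulationSettings()))
                for r in (1.11111, 1.5, 2.0, 2.5, 3.0, 100.0)]
        assert all(a < b for a, b in zip(icps, icps[1:]))

    def test_parallel_resistance_identity(self, params):
        # Ro = 10 in parallel with the reference 1.11111 Ω shunt is the
        # healthy outflow resistance, so the shunted severe brain and the
        # healthy brain settle at the same ICP
        st = SimulationSettings()
        shunted = mean_icp(simulate(params.replace(Ro=10.0),
                                    ShuntSpec.constant(1.11111), st))
        healthy = mean_icp(simulate(params, ShuntSpec.absent(), st))
        assert shunted == pytest.approx(healthy, rel=1e-5)

    def test_custom_source_hook(self, params):
        p = params.replace(**QUIET)
        trace = simulate(p, settings=SimulationSettings(t_end=5.0),
                         source=lambda t: 16000.0)
        assert np.allclose(trace.p_src, 16000.0)

    def test_repeat_runs_are_bitwise_identical(self, params):
        st = SimulationSettings(t_end=10.0)
        a = simulate(params, ShuntSpec.absent(), st)
        b = simulate(params, ShuntSpec.absent(), st)
        assert np.array_equal(a.P_ic, b.P_ic) and np.array_equal(a.q_o, b.q_o)
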