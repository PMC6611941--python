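"""Nodal assembly and time integration of the CSF circuit.

The network has three capacitors, so the state is the three capacitor
voltages (arterial–intracranial, venous–intracranial, intracranial–
reference).  The capillary node carries no compliance and is eliminated
algebraically at every instant.  The three one-way valves are ideal diodes:
a branch conducts ``max(ΔP, 0) / R`` with zero forward drop and zero reverse
leakage, which keeps the right-hand side continuous (piecewise linear), so a
standard adaptive stiff integrator needs no event handling.

Topology
--------
source → R1 → arterial node A; R2: A→C (capillary); R3: C→V (venous);
R4: V→reference; Rf + D_f: C→IC (CSF formation); (Ro + D_o) ∥
(Rshunt + D_shunt): IC→P_vs (absorption and shunt drainage, both
terminating at the sagittal-sinus reference); Cai: A↔IC; Cvi: V↔IC;
Ctiss: IC↔reference.

The intracranial equation is the statement that the total intracranial
volume is constant: the compartment volume rates (arterial, venous, tissue,
CSF) sum to zero at every instant, which is enforced exactly by
construction of the state derivative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, NamedTuple

import numpy as np
from scipy.integrate import solve_ivp

from .core import CircuitState, ModelParameters, PressureTrace, ShuntSpec
from .sources import arterial_pressure, shunt_resistance

__all__ = [
    "SimulationSettings",
    "DiodeFlags",
    "DCOperatingPoint",
    "capillary_pressure",
    "state_derivative",
    "simulate",
    "dc_steady_state",
    "conservation_residual",
]

SourceFn = Callable[[float], float]


@dataclass(frozen=True)
class SimulationSettings:
    """Integration controls: horizon, output grid and solver tolerances."""

    t_end: float = 60.0
    dt_out: float = 0.01
    rel_tol: float = 1e-8
    abs_tol: float = 1e-10
    init_mode: str = "zeros"  # zeros | dc

    def __post_init__(self) -> None:
        if self.t_end <= 0 or self.dt_out <= 0:
            raise ValueError("t_end and dt_out must be > 0")
        if self.rel_tol <= 0 or self.abs_tol <= 0:
            raise ValueError("solver tolerances must be > 0")
        if self.init_mode not in ("zeros", "dc"):
            raise ValueError(f"unknown init_mode {self.init_mode!r}")


class DiodeFlags(NamedTuple):
    """Conduction state (0/1) of the formation, absorption and shunt valves."""

    f_df: int
    f_do: int
    f_sh: int


class DCOperatingPoint(NamedTuple):
    """Node pressures of the constant-source steady state, in Pa."""

    P_a: float
    P_c: float
    P_v: float
    P_ic: float

    @property
    def state(self) -> CircuitState:
        return CircuitState.from_pressures(self.P_a, self.P_v, self.P_ic)


def capillary_pressure(P_a, P_v, P_ic, params: ModelParameters):
    """Pressure of the capillary node, eliminated algebraically.

    The node has no compliance, so its pressure balances the instantaneous
    currents: ``(P_a − P_c)/R2 = (P_c − P_v)/R3 + f_df (P_c − P_ic)/Rf``
    with the formation valve conducting iff P_c > P_ic.  Trying the
    conducting branch first and falling back to the blocked one picks the
    unique consistent solution (the balance is strictly decreasing in P_c).
    Accepts scalars or arrays.
    """
    p = params
    g_on = 1.0 / p.R2 + 1.0 / p.R3 + 1.0 / p.Rf
    g_off = 1.0 / p.R2 + 1.0 / p.R3
    pc_on = (np.asarray(P_a) / p.R2 + np.asarray(P_v) / p.R3
             + np.asarray(P_ic) / p.Rf) / g_on
    pc_off = (np.asarray(P_a) / p.R2 + np.asarray(P_v) / p.R3) / g_off
    out = np.where(pc_on > np.asarray(P_ic), pc_on, pc_off)
    return out if out.ndim else float(out)


def _branch_flows(t, P_c, P_ic, params: ModelParameters, shunt: ShuntSpec):
    """Formation, absorption and shunt flows with the diode rectification."""
    q_f = np.maximum(P_c - P_ic, 0.0) / params.Rf
    drive = P_ic - params.P_vs
    q_o = np.maximum(drive, 0.0) / params.Ro
    if shunt.kind == "absent":
        q_sh = np.zeros_like(np.asarray(drive, dtype=float))
    else:
        r_sh = shunt_resistance(t, shunt)
        q_sh = (np.maximum(drive, 0.0) if shunt.has_valve else drive) / r_sh
    return q_f, q_o, q_sh


def state_derivative(t: float, y: np.ndarray, params: ModelParameters,
                     shunt: ShuntSpec, source: SourceFn | None = None) -> np.ndarray:
    """Time derivative of the capacitor voltages ``[u_ai, u_vi, u_ic]``.

    The arterial and venous lines are current balances at nodes A and V;
    the intracranial line is volume conservation of the rigid cranium
    rearranged for dP_ic/dt.
    """
    p = params
    u_ai, u_vi, u_ic = y
    P_ic = u_ic
    P_a = u_ai + u_ic
    P_v = u_vi + u_ic
    P_c = capillary_pressure(P_a, P_v, P_ic, p)
    q_f, q_o, q_sh = _branch_flows(t, P_c, P_ic, p, shunt)
    v_src = source(t) if source is not None else arterial_pressure(t, p)

    du_ai = ((v_src - P_a) / p.R1 - (P_a - P_c) / p.R2) / p.Cai
    du_vi = ((P_c - P_v) / p.R3 - P_v / p.R4) / p.Cvi
    du_ic = (p.Cai * du_ai + p.Cvi * du_vi + q_f - q_o - q_sh) / p.Ctiss
    return np.array([du_ai, du_vi, du_ic])


def diode_flags(P_c: float, P_ic: float, params: ModelParameters,
                shunt: ShuntSpec) -> DiodeFlags:
    """Conduction flags implied by an instantaneous pressure configuration."""
    f_df = int(P_c - P_ic > 0)
    drive = P_ic - params.P_vs
    f_do = int(drive > 0)
    f_sh = int(shunt.kind != "absent" and (drive > 0 or not shunt.has_valve))
    return DiodeFlags(f_df, f_do, f_sh)


def dc_steady_state(params: ModelParameters,
                    rshunt: float | None = None) -> DCOperatingPoint:
    """Analytic steady state with the source held at its offset.

    Capacitors are open, all diodes are assumed conducting, and the shunt
    (if ``rshunt`` is given) acts in parallel with Ro, so the drainage
    branch sees the effective resistance Ro ∥ Rshunt.  Solves the 4-node
    linear current balance and verifies afterwards that every diode really
    is forward-biased; a non-conducting configuration is an error rather
    than a silently wrong answer.
    """
    p = params
    if rshunt is not None and rshunt <= 0:
        raise ValueError("rshunt must be > 0")
    r_eff = p.Ro if rshunt is None else p.Ro * rshunt / (p.Ro + rshunt)

    # unknowns x = [P_a, P_c, P_v, P_ic]
    A = np.array([
        [1.0 / p.R1 + 1.0 / p.R2, -1.0 / p.R2, 0.0, 0.0],
        [1.0 / p.R2, -(1.0 / p.R2 + 1.0 / p.R3 + 1.0 / p.Rf), 1.0 / p.R3, 1.0 / p.Rf],
        [0.0, 1.0 / p.R3, -(1.0 / p.R3 + 1.0 / p.R4), 0.0],
        [0.0, 1.0 / p.Rf, 0.0, -(1.0 / p.Rf + 1.0 / r_eff)],
    ])
    b = np.array([p.src_offset / p.R1, 0.0, 0.0, -p.P_vs / r_eff])
    P_a, P_c, P_v, P_ic = np.linalg.solve(A, b)

    if P_c - P_ic < 0 or P_ic - p.P_vs < 0:
        raise RuntimeError(
            "conducting-diode assumption fails for these parameters "
            f"(P_c−P_ic={P_c - P_ic:.3g}, P_ic−P_vs={P_ic - p.P_vs:.3g})")
    return DCOperatingPoint(float(P_a), float(P_c), float(P_v), float(P_ic))


def _initial_state(params: ModelParameters, shunt: ShuntSpec,
                   settings: SimulationSettings) -> np.ndarray:
    if settings.init_mode == "zeros":
        return np.zeros(3)
    # dc: steady state of this configuration; a time-varying shunt is
    # initialised from the pre-shunt (no-shunt) steady state, matching the
    # clinical picture of a shunt switched on against an elevated ICP.
    r = shunt.Rshunt if shunt.kind == "constant" else None
    return dc_steady_state(params, r).state.as_array()


def simulate(params: ModelParameters | None = None,
             shunt: ShuntSpec | None = None,
             settings: SimulationSettings | None = None,
             source: SourceFn | None = None,
             initial_state: CircuitState | None = None) -> PressureTrace:
    """Integrate the network and return the sampled pressure/flow trace.

    Parameters default to the healthy configuration with no shunt.  The
    optional ``source`` callable replaces the built-in arterial waveform;
    ``initial_state`` overrides the ``settings.init_mode`` choice.
    """
    p = params or ModelParameters()
    sh = shunt or ShuntSpec.absent()
    st = settings or SimulationSettings()

    y0 = (initial_state.as_array() if initial_state is not None
          else _initial_state(p, sh, st))
    t_eval = np.arange(0.0, st.t_end + st.dt_out / 2, st.dt_out)
    sol = solve_ivp(
        state_derivative, (0.0, st.t_end), y0,
        method="LSODA", rtol=st.rel_tol, atol=st.abs_tol,
        t_eval=t_eval, max_step=0.1, args=(p, sh, source),
    )
    if not sol.success:
        raise RuntimeError(f"ODE solver failed near t={sol.t[-1]:.4g} s: {sol.message}")

    u_ai, u_vi, u_ic = sol.y
    P_ic = u_ic
    P_a = u_ai + u_ic
    P_v = u_vi + u_ic
    P_c = capillary_pressure(P_a, P_v, P_ic, p)
    q_f, q_o, q_sh = _branch_flows(sol.t, P_c, P_ic, p, sh)
    p_src = (np.array([source(ti) for ti in sol.t]) if source is not None
             else arterial_pressure(sol.t, p))
    cbf = (p_src - P_a) / p.R1
    return PressureTrace(t=sol.t, P_a=P_a, P_c=P_c, P_v=P_v, P_ic=P_ic,
                         q_f=q_f, q_o=q_o, q_sh=np.broadcast_to(q_sh, P_ic.shape).copy(),
                         cbf=cbf, p_src=p_src)


def conservation_residual(trace: PressureTrace, params: ModelParameters,
                          shunt: ShuntSpec, source: SourceFn | None = None) -> np.ndarray:
    """Rigid-cranium volume-conservation residual along a trace.

    Evaluates the compartment volume rates from the instantaneous state
    derivative at every output sample and returns their sum
    (dVa/dt + dVv/dt + dVtiss/dt + dVcsf/dt), which the model requires to
    vanish identically.
    """
    p = params
    res = np.empty_like(trace.t)
    for i, ti in enumerate(trace.t):
        y = np.array([trace.P_a[i] - trace.P_ic[i],
                      trace.P_v[i] - trace.P_ic[i],
                      trace.P_ic[i]])
        du_ai, du_vi, du_ic = state_derivative(ti, y, p, shunt, source)
        res[i] = (p.Cai * du_ai + p.Cvi * du_vi - p.Ctiss * du_ic
                  + trace.q_f[i] - trace.q_o[i] - trace.q_sh[i])
    return res
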