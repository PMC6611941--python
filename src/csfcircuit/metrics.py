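"""Summary quantities: mean ICP, percent increase, shunt efficiency,
compartment volume rates, and Poiseuille shunt-design helpers."""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq

from .core import ModelParameters, PressureTrace, ShuntSpec
from .simulator import SimulationSettings, simulate

__all__ = [
    "mean_icp",
    "percent_increase",
    "shunt_efficiency",
    "volume_rates",
    "poiseuille_resistance",
    "resistance_for_efficiency",
]


def mean_icp(trace: PressureTrace, window: float = 10.0) -> float:
    """Time-averaged intracranial pressure over the final ``window`` seconds.

    The scalar "ICP" of a pulsatile run: averaging over a whole number of
    cardiac cycles after the transient has decayed gives the steady value.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    if window > trace.duration + 1e-12:
        raise ValueError("window longer than the trace")
    mask = trace.t >= trace.t[-1] - window
    return float(np.mean(trace.P_ic[mask]))


def percent_increase(icp: float, icp_healthy: float) -> float:
    """Relative ICP elevation over the healthy baseline, in percent."""
    if icp_healthy <= 0:
        raise ValueError("healthy baseline ICP must be > 0")
    return (icp / icp_healthy - 1.0) * 100.0


def shunt_efficiency(icp_after: float, icp_healthy: float, icp_before: float) -> float:
    """Shunt figure of merit, in percent.

    ``(1 − (ICP_after − ICP_healthy) / ICP_before) × 100``: 100% means the
    shunt restores the healthy ICP exactly; lower values leave a residual
    elevation scaled by the untreated (before-shunting) ICP.
    """
    if icp_before <= 0:
        raise ValueError("before-shunting ICP must be > 0")
    return (1.0 - (icp_after - icp_healthy) / icp_before) * 100.0


def volume_rates(trace: PressureTrace, params: ModelParameters) -> dict[str, np.ndarray]:
    """Compartment volume rates along a trace (arterial, venous, tissue, CSF).

    Pressure derivatives are central finite differences on the output grid;
    the CSF rate is formation minus total drainage.  In a rigid cranium the
    four rates sum to zero (up to finite-difference error).
    """
    dt_grad = np.gradient(trace.t)
    dva = params.Cai * np.gradient(trace.P_a - trace.P_ic) / dt_grad
    dvv = params.Cvi * np.gradient(trace.P_v - trace.P_ic) / dt_grad
    dvtiss = -params.Ctiss * np.gradient(trace.P_ic) / dt_grad
    dvcsf = trace.q_f - (trace.q_o + trace.q_sh)
    return {"dVa_dt": dva, "dVv_dt": dvv, "dVtiss_dt": dvtiss, "dVcsf_dt": dvcsf}


def poiseuille_resistance(mu: float, l: float, r: float) -> float:
    """Hydraulic resistance ``8 μ l / (π r⁴)`` of laminar flow in a tube.

    Maps catheter geometry (viscosity ``mu`` in Pa·s, length ``l`` and inner
    radius ``r`` in m) to the resistance relating pressure drop and flow,
    ΔP = q·R.
    """
    if mu <= 0 or l <= 0 or r <= 0:
        raise ValueError("viscosity, length and radius must be > 0")
    return 8.0 * mu * l / (np.pi * r**4)


def resistance_for_efficiency(target_eff: float,
                              params: ModelParameters | None = None,
                              settings: SimulationSettings | None = None,
                              ro_pathology: float = 10.0,
                              bracket: tuple[float, float] = (0.05, 200.0),
                              tol_pp: float = 0.1) -> float:
    """Constant shunt resistance achieving a target efficiency, by root finding.

    Baselines are simulated under identical settings: the healthy run
    (Ro = 1, no shunt) and the untreated pathological run (``ro_pathology``,
    no shunt).  Efficiency is monotone decreasing in the shunt resistance,
    so a bracketing root find converges; a target outside the attainable
    range (too low even for a huge resistance, or above what a near-zero
    resistance yields) is reported as an error.
    """
    if not 0 < target_eff <= 119:  # upper end: over-drainage beyond ICP=0
        raise ValueError("target efficiency out of range")
    p = params or ModelParameters()
    st = settings or SimulationSettings()
    healthy = mean_icp(simulate(p.replace(Ro=1.0), ShuntSpec.absent(), st))
    severe_params = p.replace(Ro=ro_pathology)
    before = mean_icp(simulate(severe_params, ShuntSpec.absent(), st))

    def gap(rsh: float) -> float:
        after = mean_icp(simulate(severe_params, ShuntSpec.constant(rsh), st))
        return shunt_efficiency(after, healthy, before) - target_eff

    lo, hi = bracket
    g_lo, g_hi = gap(lo), gap(hi)
    if g_lo * g_hi > 0:
        raise ValueError(
            f"target efficiency {target_eff}% not attainable in bracket "
            f"[{lo}, {hi}] Ω (gap {g_lo:.2f} .. {g_hi:.2f} pp)")
    return float(brentq(gap, lo, hi, xtol=tol_pp * 1e-3, rtol=1e-6))
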