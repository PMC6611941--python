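"""Named end-to-end experiments: healthy baseline, graded hydrocephalus,
constant/blocked/time-varying shunts, and the shunt-resistance sweep.

Every scenario is deterministic; percent increases are always computed
against a fresh healthy run under identical solver settings (never a
hard-coded baseline), and shunt efficiencies additionally use the
same-pathology no-shunt run, so discretisation error cancels instead of
compounding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from functools import lru_cache

import pandas as pd

from .core import ModelParameters, PressureTrace, ScenarioResult, ShuntSpec, pa_to_mmhg
from .metrics import mean_icp, percent_increase, shunt_efficiency
from .simulator import SimulationSettings, dc_steady_state, simulate

__all__ = [
    "Scenario",
    "SCENARIO_IDS",
    "SWEEP_RSHUNTS",
    "make_scenario",
    "run_scenario",
    "run_shunt_sweep",
    "run_timevarying_shunt",
]

logger = logging.getLogger(__name__)

#: Shunt resistances of the efficiency sweep, in the reported order (Ω-analog).
SWEEP_RSHUNTS = (1.11111, 1.5, 2.0, 2.5, 3.0)

#: Ro presets: healthy outflow resistance and the two hydrocephalus grades.
RO_NORMAL, RO_MODERATE, RO_SEVERE = 1.0, 5.0, 10.0


@dataclass(frozen=True)
class Scenario:
    """A named experiment: an outflow resistance, a shunt, and run settings."""

    id: str
    ro: float
    shunt: ShuntSpec
    settings: SimulationSettings = SimulationSettings()


def _scenario_defaults() -> dict[str, Scenario]:
    long = SimulationSettings()
    return {
        "normal": Scenario("normal", RO_NORMAL, ShuntSpec.absent(), long),
        "moderate": Scenario("moderate", RO_MODERATE, ShuntSpec.absent(), long),
        "severe": Scenario("severe", RO_SEVERE, ShuntSpec.absent(), long),
        "shunt_fixed": Scenario("shunt_fixed", RO_SEVERE,
                                ShuntSpec.constant(1.11111), long),
        "shunt_blocked": Scenario("shunt_blocked", RO_SEVERE,
                                  ShuntSpec.constant(100.0), long),
        "shunt_timevarying": Scenario("shunt_timevarying", RO_SEVERE,
                                      ShuntSpec.time_varying(),
                                      replace(long, t_end=15.0)),
    }


SCENARIO_IDS = tuple(_scenario_defaults())


def make_scenario(scenario_id: str, ro: float | None = None,
                  rshunt: float | None = None,
                  t_end: float | None = None) -> Scenario:
    """Look up a named scenario, optionally overriding Ro, Rshunt or t_end."""
    try:
        sc = _scenario_defaults()[scenario_id]
    except KeyError:
        raise ValueError(f"unknown scenario {scenario_id!r}; "
                         f"choose from {SCENARIO_IDS}") from None
    if ro is not None:
        sc = replace(sc, ro=ro)
    if rshunt is not None:
        sc = replace(sc, shunt=ShuntSpec.constant(rshunt))
    if t_end is not None:
        sc = replace(sc, settings=replace(sc.settings, t_end=t_end))
    return sc


@lru_cache(maxsize=64)
def _cached_run(params: ModelParameters, shunt: ShuntSpec,
                settings: SimulationSettings):
    trace = simulate(params, shunt, settings)
    return trace, mean_icp(trace)


def run_scenario(scenario: Scenario | str,
                 params: ModelParameters | None = None
                 ) -> tuple[ScenarioResult, PressureTrace]:
    """Simulate one scenario and summarise it.

    Returns the summary (mean ICP in Pa and mmHg, percent increase over the
    healthy run, and — for shunted scenarios — the shunt efficiency) together
    with the full pressure/flow trace.
    """
    if isinstance(scenario, str):
        scenario = make_scenario(scenario)
    base = params or ModelParameters()
    p = base.replace(Ro=scenario.ro)

    if scenario.shunt.kind == "time_varying":
        trace = run_timevarying_shunt(base, scenario.shunt, scenario.settings)
        icp = mean_icp(trace, window=min(10.0, trace.duration / 2))
    else:
        trace, icp = _cached_run(p, scenario.shunt, scenario.settings)

    _, icp_healthy = _cached_run(base.replace(Ro=RO_NORMAL), ShuntSpec.absent(),
                                 scenario.settings if scenario.shunt.kind != "time_varying"
                                 else SimulationSettings())
    pct = None if scenario.id == "normal" else percent_increase(icp, icp_healthy)

    eff = None
    if scenario.shunt.kind != "absent":
        _, icp_before = _cached_run(p, ShuntSpec.absent(),
                                    scenario.settings if scenario.shunt.kind != "time_varying"
                                    else SimulationSettings())
        eff = shunt_efficiency(icp, icp_healthy, icp_before)

    rshunt = scenario.shunt.Rshunt if scenario.shunt.kind == "constant" else None
    result = ScenarioResult(
        scenario_id=scenario.id,
        mean_icp=icp,
        mean_icp_mmhg=pa_to_mmhg(icp, base.pa_per_mmhg),
        percent_increase=pct,
        efficiency=eff,
        rshunt=rshunt,
        parameters=p,
    )
    logger.info("scenario %s: Ro=%g, shunt=%s -> mean ICP %.2f Pa (%.2f mmHg), "
                "readout window %.0f s", scenario.id, scenario.ro,
                scenario.shunt.kind, icp, result.mean_icp_mmhg,
                min(10.0, trace.duration / 2) if scenario.shunt.kind == "time_varying" else 10.0)
    return result, trace


def run_shunt_sweep(params: ModelParameters | None = None,
                    settings: SimulationSettings | None = None) -> pd.DataFrame:
    """Sweep the constant shunt resistance under severe hydrocephalus.

    One row per resistance in :data:`SWEEP_RSHUNTS`, with the steady mean
    ICP (Pa and mmHg) and the shunt efficiency computed from simulated
    healthy and untreated baselines.
    """
    base = params or ModelParameters()
    st = settings or SimulationSettings()
    _, icp_healthy = _cached_run(base.replace(Ro=RO_NORMAL), ShuntSpec.absent(), st)
    severe = base.replace(Ro=RO_SEVERE)
    _, icp_before = _cached_run(severe, ShuntSpec.absent(), st)

    rows = []
    for rsh in SWEEP_RSHUNTS:
        _, icp = _cached_run(severe, ShuntSpec.constant(rsh), st)
        rows.append({
            "rshunt_ohm": rsh,
            "icp_pa": icp,
            "icp_mmhg": pa_to_mmhg(icp, base.pa_per_mmhg),
            "efficiency_pct": shunt_efficiency(icp, icp_healthy, icp_before),
        })
    return pd.DataFrame(rows)


def run_timevarying_shunt(params: ModelParameters | None = None,
                          spec: ShuntSpec | None = None,
                          settings: SimulationSettings | None = None) -> PressureTrace:
    """Severe hydrocephalus treated by the failing (time-varying) shunt.

    Starts from the untreated severe steady state — the shunt is switched on
    against an already elevated ICP — and integrates 15 s by default,
    long enough to cover the valve's closed, open and over-draining phases.
    """
    base = params or ModelParameters()
    p = base.replace(Ro=RO_SEVERE)
    sh = spec or ShuntSpec.time_varying()
    st = settings or SimulationSettings(t_end=15.0)
    init = dc_steady_state(p).state
    logger.info("time-varying shunt run: init ICP %.1f Pa, t_end %.1f s",
                init.P_ic, st.t_end)
    return simulate(p, sh, st, initial_state=init)
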