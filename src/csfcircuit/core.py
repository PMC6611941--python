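"""Parameters, unit conversions and result containers for the CSF circuit model.

The model is an electrical analog of cerebrospinal-fluid (CSF) dynamics:
pressures are voltages (Pa), flows are currents (Pa/Ω-analog), vessel and
tissue compliances are capacitors, and one-way valves (the choroid-plexus
secretion pathway, the arachnoid granulations, the shunt valve) are ideal
diodes.  Hydrocephalus is an increase of the CSF outflow resistance ``Ro``;
a shunt is a low-resistance bypass in parallel with it.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "PA_PER_MMHG",
    "ModelParameters",
    "ShuntSpec",
    "CircuitState",
    "PressureTrace",
    "ScenarioResult",
    "pa_to_mmhg",
    "mmhg_to_pa",
    "ohm_to_hydraulic_resistance",
    "load_parameters",
]

#: Pa per mmHg, the conversion the model's own Pa/mmHg value pairs imply.
PA_PER_MMHG = 133.322


@dataclass(frozen=True)
class ModelParameters:
    """Circuit element values and source constants.

    Resistances are in the model's Ω-analog scale (1 Ω-analog ≈ 8 mmHg/ml/min
    of hydraulic resistance), compliances in F-analog, pressures in Pa.

    Attributes
    ----------
    R1 : float
        Source series resistance shaping the arterial pressure waveform.
    R2, R3, R4 : float
        Arterial, capillary and venous resistances of the blood pathway.
    Rf : float
        Resistance of the CSF formation pathway (arterial blood to choroid
        plexus), in series with an ideal diode.
    Ro : float
        Resistance to CSF outflow through the arachnoid villi: 1 for a
        healthy subject, 5 for moderate and 10 for severe hydrocephalus.
    Cai, Cvi, Ctiss : float
        Compliances between arteries and the intracranial space, veins and
        the intracranial space, and of the brain tissue itself.
    src_amp1, src_amp2, src_offset, src_f1, src_f2, src_phase1 : float
        Constants of the pulsatile arterial source: two sinusoids (1 Hz and
        2 Hz at defaults) subtracted on top of a constant offset.
    P_vs : float
        Terminal pressure of the drainage branches (sagittal sinus side of
        the arachnoid villi and of the shunt), relative to reference.
    ohm_to_hydraulic : float
        Hydraulic resistance (mmHg/ml/min) equivalent to 1 Ω-analog.
    pa_per_mmhg : float
        Unit conversion, Pa per mmHg.
    """

    R1: float = 6.0
    R2: float = 2.5
    R3: float = 3.25
    R4: float = 3.0
    Rf: float = 5.0
    Ro: float = 1.0
    Cai: float = 0.1
    Cvi: float = 0.1
    Ctiss: float = 0.1
    src_amp1: float = 17.0
    src_amp2: float = 12.5
    src_offset: float = 16000.0
    src_f1: float = 1.0
    src_f2: float = 2.0
    src_phase1: float = -math.pi / 2
    P_vs: float = 0.0
    ohm_to_hydraulic: float = 8.0
    pa_per_mmhg: float = PA_PER_MMHG

    def __post_init__(self) -> None:
        for name in ("R1", "R2", "R3", "R4", "Rf", "Ro"):
            if getattr(self, name) <= 0:
                raise ValueError(f"resistance {name} must be > 0")
        for name in ("Cai", "Cvi", "Ctiss"):
            if getattr(self, name) <= 0:
                raise ValueError(f"compliance {name} must be > 0")
        if self.src_f1 <= 0 or self.src_f2 <= 0:
            raise ValueError("source frequencies must be > 0")
        if self.pa_per_mmhg <= 0 or self.ohm_to_hydraulic < 0:
            raise ValueError("conversion constants out of range")

    def replace(self, **changes: float) -> "ModelParameters":
        """Return a copy with the given fields overridden."""
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class ShuntSpec:
    """A hydrocephalus shunt: a drainage resistance in series with a valve.

    ``kind`` selects between no shunt, a constant resistance, and a
    time-varying resistance ``tv_amp * exp(-tv_decay * t) * (tv_offset +
    sin(t))`` that emulates valve flutter and progressive lumen change.
    ``has_valve`` adds the ideal one-way valve (no backflow into the
    ventricles).
    """

    kind: str = "absent"  # absent | constant | time_varying
    Rshunt: float = 1.11111
    tv_amp: float = 15.0
    tv_decay: float = 0.3
    tv_offset: float = 1.2
    has_valve: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("absent", "constant", "time_varying"):
            raise ValueError(f"unknown shunt kind {self.kind!r}")
        if self.kind == "constant" and self.Rshunt <= 0:
            raise ValueError("constant shunt resistance must be > 0")
        if self.kind == "time_varying":
            if self.tv_amp <= 0:
                raise ValueError("tv_amp must be > 0")
            if self.tv_offset <= 1:
                raise ValueError("tv_offset must be > 1 so the resistance stays positive")

    @classmethod
    def absent(cls) -> "ShuntSpec":
        return cls(kind="absent")

    @classmethod
    def constant(cls, Rshunt: float, has_valve: bool = True) -> "ShuntSpec":
        return cls(kind="constant", Rshunt=Rshunt, has_valve=has_valve)

    @classmethod
    def time_varying(cls, tv_amp: float = 15.0, tv_decay: float = 0.3,
                     tv_offset: float = 1.2, has_valve: bool = True) -> "ShuntSpec":
        return cls(kind="time_varying", tv_amp=tv_amp, tv_decay=tv_decay,
                   tv_offset=tv_offset, has_valve=has_valve)


@dataclass(frozen=True)
class CircuitState:
    """The three independent capacitor voltages of the network.

    ``u_ai`` and ``u_vi`` are the arterial–intracranial and
    venous–intracranial pressure differences; ``u_ic`` is the intracranial
    pressure relative to reference.  The capillary node carries no
    compliance, so its pressure is algebraic and not part of the state.
    """

    u_ai: float
    u_vi: float
    u_ic: float

    @property
    def P_ic(self) -> float:
        return self.u_ic

    @property
    def P_a(self) -> float:
        return self.u_ai + self.u_ic

    @property
    def P_v(self) -> float:
        return self.u_vi + self.u_ic

    def as_array(self) -> np.ndarray:
        return np.array([self.u_ai, self.u_vi, self.u_ic], dtype=float)

    @classmethod
    def from_pressures(cls, P_a: float, P_v: float, P_ic: float) -> "CircuitState":
        return cls(u_ai=P_a - P_ic, u_vi=P_v - P_ic, u_ic=P_ic)


@dataclass
class PressureTrace:
    """Simulated node pressures and branch flows on a uniform time grid.

    All pressures in Pa, flows in the Pa/Ω analog of ml/min.  ``q_f`` is the
    CSF formation flow, ``q_o`` the arachnoid-villi absorption flow, ``q_sh``
    the shunt flow and ``cbf`` the cerebral blood flow (the current through
    the source series resistance).  ``p_src`` is the raw source waveform,
    recorded alongside the post-source arterial node pressure ``P_a``.
    """

    t: np.ndarray
    P_a: np.ndarray
    P_c: np.ndarray
    P_v: np.ndarray
    P_ic: np.ndarray
    q_f: np.ndarray
    q_o: np.ndarray
    q_sh: np.ndarray
    cbf: np.ndarray
    p_src: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.t) < 2 or np.any(np.diff(self.t) <= 0):
            raise ValueError("time grid must be strictly increasing")

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t": self.t, "P_a": self.P_a, "P_c": self.P_c, "P_v": self.P_v,
            "P_ic": self.P_ic, "q_f": self.q_f, "q_o": self.q_o,
            "q_sh": self.q_sh, "cbf": self.cbf,
        })

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class ScenarioResult:
    """Summary metrics of one scenario run."""

    scenario_id: str
    mean_icp: float
    mean_icp_mmhg: float
    percent_increase: float | None = None
    efficiency: float | None = None
    rshunt: float | None = None
    parameters: ModelParameters | None = None

    def to_dict(self) -> dict:
        return {
            "scenario_id": self.scenario_id,
            "mean_icp_pa": self.mean_icp,
            "mean_icp_mmhg": self.mean_icp_mmhg,
            "percent_increase": self.percent_increase,
            "efficiency": self.efficiency,
            "rshunt": self.rshunt,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def pa_to_mmhg(p: float | np.ndarray, pa_per_mmhg: float = PA_PER_MMHG):
    """Convert a pressure from Pa to mmHg."""
    return p / pa_per_mmhg


def mmhg_to_pa(p: float | np.ndarray, pa_per_mmhg: float = PA_PER_MMHG):
    """Convert a pressure from mmHg to Pa."""
    return p * pa_per_mmhg


def ohm_to_hydraulic_resistance(R: float, params: ModelParameters | None = None) -> float:
    """Map an Ω-analog resistance to hydraulic units (mmHg/ml/min).

    The calibration is the model's anchor that 1 Ω-analog of CSF outflow
    resistance corresponds to about 8 mmHg/ml/min in a healthy subject.
    """
    if R < 0:
        raise ValueError("resistance must be >= 0")
    factor = params.ohm_to_hydraulic if params is not None else 8.0
    return factor * R


_PARAM_FIELDS = {f.name for f in dataclasses.fields(ModelParameters)}


def load_parameters(source: str | Path | Mapping[str, float],
                    base: ModelParameters | None = None) -> ModelParameters:
    """Build :class:`ModelParameters` from a flat key→value config.

    ``source`` is a YAML file path (flat mapping, keys named exactly as the
    parameter fields) or an already-parsed mapping.  Unknown keys are
    rejected; unspecified fields keep the defaults of ``base``.
    """
    if isinstance(source, (str, Path)):
        data = yaml.safe_load(Path(source).read_text())
        if data is None:
            data = {}
    else:
        data = dict(source)
    if not isinstance(data, dict):
        raise ValueError("parameter config must be a flat key: value mapping")
    unknown = set(data) - _PARAM_FIELDS
    if unknown:
        raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
    base = base or ModelParameters()
    return base.replace(**{k: float(v) for k, v in data.items()})
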