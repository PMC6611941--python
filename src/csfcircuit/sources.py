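"""Time-dependent inputs: the arterial pressure source and the shunt resistance.

The arterial driver mimics the cerebral arterial blood-pressure waveform by
subtracting a 2 Hz sinusoid from a 1 Hz sinusoid on top of a constant
offset; the result is 1-periodic at the default frequencies.  The
time-varying shunt resistance emulates a failing valve: an exponentially
decaying envelope (progressive lumen opening) modulated by ``sin(t)``
(irregular opening and closing of the valve).
"""

from __future__ import annotations

import numpy as np

from .core import ModelParameters, ShuntSpec

__all__ = ["arterial_pressure", "shunt_resistance"]


def arterial_pressure(t, params: ModelParameters | None = None):
    """Pulsatile arterial source pressure at time ``t`` (seconds), in Pa.

    ``amp1 * sin(2π f1 t + phase1) - amp2 * sin(2π f2 t) + offset``.
    Accepts scalars or arrays.
    """
    p = params or ModelParameters()
    t = np.asarray(t, dtype=float)
    out = (p.src_amp1 * np.sin(2 * np.pi * p.src_f1 * t + p.src_phase1)
           - p.src_amp2 * np.sin(2 * np.pi * p.src_f2 * t)
           + p.src_offset)
    return out if out.ndim else float(out)


def shunt_resistance(t, spec: ShuntSpec):
    """Shunt resistance (Ω-analog) at time ``t`` (seconds).

    Constant shunts ignore ``t``; the time-varying law is
    ``tv_amp * exp(-tv_decay t) * (tv_offset + sin t)`` with ``t`` in
    radian-seconds, positive for all finite ``t`` when ``tv_offset > 1``.
    Querying an absent shunt is a usage error.
    """
    if spec.kind == "absent":
        raise ValueError("no shunt present: resistance undefined")
    t = np.asarray(t, dtype=float)
    if spec.kind == "constant":
        out = np.full_like(t, spec.Rshunt)
    else:
        out = spec.tv_amp * np.exp(-spec.tv_decay * t) * (spec.tv_offset + np.sin(t))
    return out if out.ndim else float(out)
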