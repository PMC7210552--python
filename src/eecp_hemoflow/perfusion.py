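"""Volumetric flow rate and per-cycle perfusion from Doppler-style waveforms.

The flow rate combines the velocity waveform v(t) and lumen diameter
waveform d(t) measured at the common carotid:

    Q(t) = profile_factor * v(t) * pi d(t)^2 / 4

``profile_factor`` encodes what the velocity trace represents: 1.0 for a
cross-section mean velocity (default), 0.5 for a Doppler peak velocity
under a parabolic profile.  Per-cycle perfusion is the trapezoidal
integral of Q over one period.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .synthdata.waveforms import Waveform

__all__ = ["PerfusionResult", "flow_rate", "cycle_perfusion", "perfusion_change"]

_COMMON_GRID = 512


@dataclass(frozen=True)
class PerfusionResult:
    Q: Waveform  # m^3/s
    volume: float  # m^3 per cycle
    mean_flow: float  # m^3/s

    @property
    def volume_ml(self) -> float:
        return self.volume * 1e6


def flow_rate(
    v: Waveform, d: Waveform, profile_factor: float = 1.0
) -> Waveform:
    """Flow-rate waveform Q(t) = factor * v(t) * pi d(t)^2 / 4.

    Velocity and diameter sampled on different grids are resampled to a
    common 512-point grid (with a warning).
    """
    if not np.isclose(v.period, d.period):
        raise ValueError("velocity and diameter waveforms must share one period")
    if np.any(d.values <= 0):
        raise ValueError("diameter waveform must be strictly positive")
    if v.n_samples != d.n_samples or not np.allclose(v.t, d.t):
        warnings.warn(
            "velocity/diameter grids differ; resampling to a common grid",
            stacklevel=2,
        )
        v = v.resampled(_COMMON_GRID)
        d = d.resampled(_COMMON_GRID)
    q = profile_factor * v.values * np.pi * d.values**2 / 4.0
    return Waveform(t=v.t, values=q, period=v.period)


def cycle_perfusion(Q: Waveform) -> PerfusionResult:
    """Per-cycle perfused volume (trapezoid over one period) and mean flow."""
    mean_q = Q.cycle_mean()
    volume = mean_q * Q.period
    return PerfusionResult(Q=Q, volume=volume, mean_flow=mean_q)


def perfusion_change(pre: PerfusionResult, during: PerfusionResult) -> float:
    """Percent elevation of per-cycle perfusion, during vs pre."""
    if not np.isclose(pre.Q.period, during.Q.period):
        raise ValueError("states must be compared over the same cardiac period")
    if pre.volume == 0:
        raise ValueError("pre-state volume is zero; change undefined")
    return (during.volume - pre.volume) / pre.volume * 100.0
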