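"""Synthetic carotid velocity and diameter waveforms.

The common carotid (CCA) Doppler velocity trace over one cardiac cycle is
modelled as a non-negative baseline plus smooth periodic Gaussian bumps:
one systolic peak, and — for the during-counterpulsation state — an
additional diastolic augmentation peak produced by cuff inflation. The
bump form is chosen for its closed-form cycle integral, so the cycle-mean
velocity of any generated waveform is analytically checkable:

    mean = baseline + sum_i amplitude_i * sigma_i * sqrt(2*pi) / T

(the periodic summation of a Gaussian integrates, over one period, to the
full-line Gaussian integral).

Lumen diameter is modelled as a mild pulsation of the mean diameter,
bounded by ``mean * (1 +/- pulsation_frac)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Waveform",
    "WaveformSpec",
    "generate_velocity_waveform",
    "generate_diameter_waveform",
]

# periodicized Gaussian: sum over this many neighbouring periods (tails of a
# bump with sigma <= 0.1 T are < 1e-18 three periods away)
_N_WRAP = 3


@dataclass(frozen=True)
class Waveform:
    """A periodic sampled function of time over one cardiac cycle.

    ``t`` holds ``n`` uniform samples on ``[0, T)``; the value at ``t = T``
    equals the value at ``t = 0`` (periodic closure).
    """

    t: np.ndarray
    values: np.ndarray
    period: float

    def __post_init__(self) -> None:
        if self.t.shape != self.values.shape:
            raise ValueError("t and values must have the same shape")
        if self.period <= 0:
            raise ValueError("period must be positive")

    @property
    def n_samples(self) -> int:
        return self.t.size

    def __call__(self, t: np.ndarray | float) -> np.ndarray | float:
        """Evaluate by periodic linear interpolation."""
        tq = np.asarray(t, dtype=float) % self.period
        tp = np.concatenate([self.t, [self.period]])
        vp = np.concatenate([self.values, [self.values[0]]])
        out = np.interp(tq, tp, vp)
        return out if np.ndim(t) else float(out)

    def cycle_mean(self) -> float:
        """Cycle average by trapezoidal quadrature with periodic closure."""
        vp = np.concatenate([self.values, [self.values[0]]])
        tp = np.concatenate([self.t, [self.period]])
        return float(np.trapezoid(vp, tp) / self.period)

    def resampled(self, n: int) -> "Waveform":
        tn = np.linspace(0.0, self.period, n, endpoint=False)
        return Waveform(t=tn, values=np.asarray(self(tn)), period=self.period)

    def to_csv(self, path) -> None:
        np.savetxt(
            path,
            np.column_stack([self.t, self.values]),
            delimiter=",",
            header="t_seconds,value",
            comments="",
        )

    @classmethod
    def from_csv(cls, path, period: float | None = None) -> "Waveform":
        arr = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        t, v = arr[:, 0], arr[:, 1]
        if period is None:
            # assume uniform sampling over [0, T)
            period = float(t[-1] + (t[1] - t[0]))
        return cls(t=t, values=v, period=period)


@dataclass(frozen=True)
class WaveformSpec:
    """Parameters of the synthetic CCA velocity waveform.

    Defaults describe a resting adult CCA trace: cycle 0.8 s, systolic peak
    0.8 m/s at 0.12 T over a 0.2 m/s baseline.  The diastolic augmentation
    peak (during counterpulsation) defaults to 0.35 m/s centred at 0.56 T,
    the midpoint of the 0.54 T / 0.58 T diastolic report instants.
    """

    period_T: float = 0.8  # s
    systolic_peak_velocity: float = 0.8  # m/s, amplitude above baseline
    systolic_peak_time_frac: float = 0.12
    systolic_width_frac: float = 0.045  # Gaussian sigma as fraction of T
    diastolic_augmentation_amplitude: float = 0.35  # m/s
    diastolic_peak_time_frac: float = 0.56
    diastolic_width_frac: float = 0.06
    baseline_velocity: float = 0.2  # m/s
    n_samples: int = 400
    seed: int = 0

    def __post_init__(self) -> None:
        if self.period_T <= 0:
            raise ValueError("period_T must be positive")
        if self.n_samples < 32:
            raise ValueError("n_samples must be at least 32")
        if not 0 < self.systolic_peak_time_frac < 1:
            raise ValueError("systolic_peak_time_frac must lie in (0, 1)")
        if not 0 < self.diastolic_peak_time_frac < 1:
            raise ValueError("diastolic_peak_time_frac must lie in (0, 1)")
        if self.systolic_peak_time_frac >= self.diastolic_peak_time_frac:
            raise ValueError(
                "systolic peak must precede the diastolic peak: got systolic "
                f"fraction {self.systolic_peak_time_frac} >= diastolic "
                f"fraction {self.diastolic_peak_time_frac}"
            )
        if self.diastolic_augmentation_amplitude < 0:
            raise ValueError("diastolic_augmentation_amplitude must be >= 0")
        if self.baseline_velocity < 0 or self.systolic_peak_velocity < 0:
            raise ValueError("velocities must be non-negative")


def _periodic_gaussian(t: np.ndarray, center: float, sigma: float, T: float) -> np.ndarray:
    """Gaussian bump wrapped onto the circle of circumference T, peak 1."""
    out = np.zeros_like(t)
    for k in range(-_N_WRAP, _N_WRAP + 1):
        out += np.exp(-0.5 * ((t - center - k * T) / sigma) ** 2)
    return out


def velocity_waveform_mean(spec: WaveformSpec, state: str = "pre") -> float:
    """Closed-form cycle-mean of the generated velocity waveform (m/s)."""
    T = spec.period_T
    mean = spec.baseline_velocity
    mean += (
        spec.systolic_peak_velocity
        * spec.systolic_width_frac * T * np.sqrt(2 * np.pi) / T
    )
    if state == "during":
        mean += (
            spec.diastolic_augmentation_amplitude
            * spec.diastolic_width_frac * T * np.sqrt(2 * np.pi) / T
        )
    return float(mean)


def generate_velocity_waveform(spec: WaveformSpec, state: str = "pre") -> Waveform:
    """Generate the CCA velocity waveform for the rest ("pre") or
    counterpulsation ("during") state.

    The during-state waveform equals the pre-state waveform plus a single
    non-negative diastolic bump, so it majorizes the pre waveform and the
    two coincide when the augmentation amplitude is zero.
    """
    if state not in ("pre", "during"):
        raise ValueError(f"state must be 'pre' or 'during', got {state!r}")
    T = spec.period_T
    t = np.linspace(0.0, T, spec.n_samples, endpoint=False)
    v = np.full_like(t, spec.baseline_velocity)
    v += spec.systolic_peak_velocity * _periodic_gaussian(
        t, spec.systolic_peak_time_frac * T, spec.systolic_width_frac * T, T
    )
    if state == "during":
        v += spec.diastolic_augmentation_amplitude * _periodic_gaussian(
            t, spec.diastolic_peak_time_frac * T, spec.diastolic_width_frac * T, T
        )
    return Waveform(t=t, values=v, period=T)


def generate_diameter_waveform(
    spec: WaveformSpec, mean_diameter: float, pulsation_frac: float
) -> Waveform:
    """Generate a mildly pulsatile lumen-diameter waveform.

    The diameter swells around the systolic peak (vessel distension follows
    the pressure pulse) and satisfies
    ``mean*(1-pulsation_frac) <= d(t) <= mean*(1+pulsation_frac)`` exactly.
    """
    if mean_diameter <= 0:
        raise ValueError("mean_diameter must be positive")
    if not 0 <= pulsation_frac <= 0.2:
        raise ValueError("pulsation_frac must lie in [0, 0.2]")
    T = spec.period_T
    t = np.linspace(0.0, T, spec.n_samples, endpoint=False)
    # distension lags the velocity peak slightly, as in measured traces
    bump = _periodic_gaussian(
        t, (spec.systolic_peak_time_frac + 0.04) * T, 0.1 * T, T
    )
    shape = 2.0 * bump / bump.max() - 1.0 if bump.max() > 0 else np.zeros_like(t)
    d = mean_diameter * (1.0 + pulsation_frac * shape)
    return Waveform(t=t, values=d, period=T)
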