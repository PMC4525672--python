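"""Chest-pressure waveforms for ventilation and physiotherapy maneuvers.

The model input is a single homogeneous pressure on the chest wall.
Quiet breathing is a sinusoidal negative pressure

``P_ext(t) = P_v (1 - cos(2 pi t / 5)) / 2``        (0.2 Hz, P_v = -5 cmH2O)

always active.  A maneuver adds a non-negative term during the session:

* manual chest physiotherapy: ``P_cp max(sin(2 pi t / 5), 0)`` -- a
  positive push once per breathing cycle;
* high-frequency chest wall oscillation (HFCWO):
  ``P_s + (P_o / 2) sin(2 pi f t)`` -- a static bias plus a fast
  oscillation.  Chest-compression (CC) devices use ``P_s > 0``; focused
  pulse (FPT) devices use ``P_s = 0`` with equivalent piston pressures.

The maneuver term is zero outside the session window and multiplied by
a linear ramp at its start and end; the ventilation term is never
ramped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

VENTILATION_PERIOD = 5.0  # s (0.2 Hz)


@dataclass(frozen=True)
class SessionSchedule:
    """Timing of a maneuver session within a run."""

    duration: float = 230.0
    lead_in: float = 10.0  # ventilation only before this time
    ramp_up_end: float = 15.0
    ramp_down_start: float = 215.0
    tail_start: float = 220.0  # ventilation only after this time

    def __post_init__(self) -> None:
        seq = (
            0.0,
            self.lead_in,
            self.ramp_up_end,
            self.ramp_down_start,
            self.tail_start,
            self.duration,
        )
        if any(b < a for a, b in zip(seq, seq[1:])):
            raise ValueError("schedule windows must be ordered within the duration")

    def envelope(self, t: np.ndarray) -> np.ndarray:
        """Linear ramp factor in [0, 1] applied to the maneuver term."""
        t = np.asarray(t, dtype=float)
        up = np.clip(
            (t - self.lead_in) / max(self.ramp_up_end - self.lead_in, 1e-300),
            0.0,
            1.0,
        )
        down = np.clip(
            (self.tail_start - t)
            / max(self.tail_start - self.ramp_down_start, 1e-300),
            0.0,
            1.0,
        )
        return np.minimum(up, down)


@dataclass(frozen=True)
class ManeuverSpec:
    """A chest-pressure waveform: family plus amplitudes, all in Pa."""

    family: str = "ventilation"  # ventilation | manual | hfcwo
    P_v: float = -490.35  # ventilation amplitude (-5 cmH2O)
    P_cp: float = 0.0  # manual push amplitude
    P_s: float = 0.0  # HFCWO static pressure
    P_o: float = 0.0  # HFCWO oscillation amplitude (peak to peak)
    f: float = 20.0  # HFCWO frequency, Hz
    session: SessionSchedule = field(default_factory=SessionSchedule)

    def __post_init__(self) -> None:
        if self.family not in ("ventilation", "manual", "hfcwo"):
            raise ValueError(f"unknown maneuver family {self.family!r}")
        if self.P_v > 0:
            raise ValueError("ventilation amplitude must be <= 0 (negative pressure)")
        if min(self.P_cp, self.P_s, self.P_o) < 0:
            raise ValueError("maneuver amplitudes must be >= 0")
        if self.family == "hfcwo" and self.f <= 0:
            raise ValueError("oscillation frequency must be positive")


def external_pressure(spec: ManeuverSpec, t: float | np.ndarray) -> float | np.ndarray:
    """Chest-wall pressure (Pa) at time(s) ``t`` (s)."""
    t = np.asarray(t, dtype=float)
    omega = 2.0 * np.pi / VENTILATION_PERIOD
    p = spec.P_v * (1.0 - np.cos(omega * t)) / 2.0
    if spec.family == "manual" and spec.P_cp > 0:
        term = spec.P_cp * np.maximum(np.sin(omega * t), 0.0)
        p = p + spec.session.envelope(t) * term
    elif spec.family == "hfcwo":
        term = spec.P_s + spec.P_o / 2.0 * np.sin(2.0 * np.pi * spec.f * t)
        p = p + spec.session.envelope(t) * term
    if p.ndim == 0:
        return float(p)
    return p
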