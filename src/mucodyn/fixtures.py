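"""Initial mucus distributions and ready-made scenario presets.

The default profile models a lung with excess secretions around
generation eight: a homogeneous 10% fill of the bronchus lumen over
generations 0-5, a rise through generations 6-7 to a 50% peak at
generation 8, then a decay to zero at generation 16.  The rise and
decay values are fixed constants, chosen once so that the mean mucus
position of the profile on the rest-state tree is 7.34, and frozen
here; they are not recomputed at run time.

Presets bundle a maneuver, a mucus profile and stepper settings for the
standard numerical experiments (manual pressure sweeps, the HFCWO
example, and the static/amplitude/frequency sweeps).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

from mucodyn.dynamics import StepperConfig
from mucodyn.maneuvers import ManeuverSpec, SessionSchedule
from mucodyn.tree_geometry import N_CONDUCTING
from mucodyn.units import from_cmH2O

# Fractional fill of the bronchus lumen, generations 0..16.  The rise
# (z = 6, 7) is fixed at 0.20/0.35; the decay over z = 9..15 is
# 0.5 exp(-lambda (z - 8)) with lambda = 0.3757084313795437, the value
# that places the rest-state mean mucus position at 7.34.  Frozen
# calibration constants (see module docstring).
_DEFAULT_FILL = (
    0.10, 0.10, 0.10, 0.10, 0.10, 0.10,
    0.20, 0.35,
    0.50,
    0.343401, 0.235849, 0.161982, 0.111249, 0.076406, 0.052476, 0.036041,
    0.0,
)


@dataclass(frozen=True)
class MucusProfile:
    """Per-generation mucus cross-section fractions at rest.

    ``fill[z] = (S_b - S_a) / S_b`` for the 17 conducting generations;
    every entry lies in ``[0, 1)``.
    """

    fill: tuple = field(default_factory=lambda: _DEFAULT_FILL)
    name: str = "default"

    def __post_init__(self) -> None:
        if len(self.fill) != N_CONDUCTING:
            raise ValueError("a profile has 17 conducting-generation fills")
        arr = np.asarray(self.fill, dtype=float)
        if np.any(arr < 0) or np.any(arr >= 1):
            raise ValueError("fill fractions must lie in [0, 1)")

    @property
    def fill_array(self) -> np.ndarray:
        return np.asarray(self.fill, dtype=float)

    def to_csv(self) -> str:
        buf = io.StringIO()
        buf.write("generation,fill\n")
        for z, f in enumerate(self.fill):
            buf.write(f"{z},{f!r}\n")
        return buf.getvalue()

    @classmethod
    def from_csv(cls, text: str, name: str = "custom") -> "MucusProfile":
        rows = [ln for ln in text.strip().splitlines()[1:] if ln]
        fill = [0.0] * N_CONDUCTING
        for row in rows:
            z_s, f_s = row.split(",")
            fill[int(z_s)] = float(f_s)
        return cls(fill=tuple(fill), name=name)


def default_mucus_profile() -> MucusProfile:
    """The standard excess-secretions-at-generation-8 profile."""
    return MucusProfile()


def zero_mucus_profile() -> MucusProfile:
    """A mucus-free lung (air lumen equals bronchus lumen everywhere)."""
    return MucusProfile(fill=(0.0,) * N_CONDUCTING, name="zero")


_PRESETS = ("manual_sweep", "hfcwo_example", "static_sweep", "amplitude_sweep",
            "frequency_sweep", "ventilation")


def scenario_preset(
    name: str,
    pcp_cmH2O: float = 20.0,
    ps_cmH2O: float | None = None,
    po_cmH2O: float = 1.2,
    freq_hz: float = 20.0,
    duration: float | None = None,
) -> tuple[ManeuverSpec, MucusProfile, StepperConfig]:
    """Fully specified inputs for one of the standard experiments.

    ``manual_sweep``: manual physiotherapy at amplitude ``pcp_cmH2O``.
    ``hfcwo_example``: CC device, P_s = 5.6, P_o = 1.2 cmH2O, 20 Hz.
    ``static_sweep``: HFCWO with P_o = 1.2 cmH2O, 20 Hz, variable P_s.
    ``amplitude_sweep``: HFCWO with P_s = 0.6 cmH2O (total oscillates
    between 0 and 1.2 cmH2O at the default P_o), variable P_o.
    ``frequency_sweep``: HFCWO with P_s = 0.6, P_o = 1.2 cmH2O,
    variable frequency.
    ``ventilation``: quiet breathing only.
    """
    if name not in _PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {_PRESETS}")
    session = SessionSchedule() if duration is None else _scaled_session(duration)
    profile = default_mucus_profile()
    cfg = StepperConfig()
    if name == "ventilation":
        spec = ManeuverSpec(family="ventilation", session=session)
    elif name == "manual_sweep":
        spec = ManeuverSpec(
            family="manual", P_cp=from_cmH2O(pcp_cmH2O), session=session
        )
    else:
        if ps_cmH2O is None:
            ps_cmH2O = {"hfcwo_example": 5.6, "static_sweep": 5.6}.get(name, 0.6)
        spec = ManeuverSpec(
            family="hfcwo",
            P_s=from_cmH2O(ps_cmH2O),
            P_o=from_cmH2O(po_cmH2O),
            f=freq_hz,
            session=session,
        )
    return spec, profile, cfg


def _scaled_session(duration: float) -> SessionSchedule:
    """Shorten a session while keeping the 10 s lead-in/tail and 5 s ramps."""
    if duration >= 230.0:
        return SessionSchedule(duration=duration,
                               ramp_down_start=duration - 15.0,
                               tail_start=duration - 10.0)
    if duration < 40.0:
        raise ValueError("sessions shorter than 40 s leave no maneuver window")
    return SessionSchedule(
        duration=duration,
        lead_in=10.0,
        ramp_up_end=15.0,
        ramp_down_start=duration - 15.0,
        tail_start=duration - 10.0,
    )
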