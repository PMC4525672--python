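"""Unit conventions.

All internal quantities are strict SI (m, m^2, m^3, Pa, s).  Pressures at
user-facing boundaries (configs, CLI flags, maneuver amplitudes) are in
cmH2O and converted once on entry with the conventional factor
1 cmH2O = 98.07 Pa.
"""

#: Pascals per centimetre of water column.
CMH2O_PA: float = 98.07


def from_cmH2O(p: float) -> float:
    """Convert a pressure from cmH2O to Pa."""
    return p * CMH2O_PA


def to_cmH2O(p: float) -> float:
    """Convert a pressure from Pa to cmH2O."""
    return p / CMH2O_PA
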