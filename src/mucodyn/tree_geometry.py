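"""Idealized 23-generation symmetric bronchial tree.

The tree bifurcates symmetrically: generation ``z`` holds ``2**z``
identical cylindrical airways.  Generations 0-16 are the conducting
airways, with lengths/reference diameters and sigmoidal pressure-area
constants tabulated per generation; generations 17-22 are the acinar
alveolar ducts (length 0.7 mm, 58 alveoli each), whose mechanics follow
the respiratory-system pressure-volume curve rather than the airway
pressure-area law.

Per-generation maximal lumen areas ``A_m`` are *generation-summed*: they
are the total lumen area of all ``2**z`` airways of the generation.  The
per-airway area is ``A_m / 2**z``.  Reference diameters are metadata
only; live areas always come from the pressure-area law.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

N_GENERATIONS = 23
N_CONDUCTING = 17  # generations 0..16
ACINAR_DUCT_LENGTH = 0.7e-3  # m
ALVEOLI_PER_DUCT = 58
TOTAL_ALVEOLI = 480e6
DUCTS_PER_ACINUS = 63  # 2**6 - 1
N_ADU_TOTAL = 2**17 * 63  # alveolar duct units in the whole tree
DEFAULT_ALPHA_DUCT = 0.17  # duct volume fraction of an alveolar duct unit


@dataclass(frozen=True)
class AirwayGenerationSpec:
    """Geometry and wall-law constants for one tree generation.

    For conducting generations (``z <= 16``) the five pressure-area
    constants are present; for acinar generations they are ``None`` and
    ``n_alv = 58``.
    """

    z: int
    length: float  # m
    ref_diameter: float | None  # m, conducting only (metadata)
    alpha0: float | None
    alpha0_prime: float | None  # 1/Pa
    n1: float | None
    n2: float | None
    A_m: float | None  # m^2, summed over the 2**z airways
    n_alv: int

    def __post_init__(self) -> None:
        if not 0 <= self.z <= 22:
            raise ValueError(f"generation index {self.z} outside 0..22")
        if self.length <= 0:
            raise ValueError("airway length must be positive")
        if self.z <= 16:
            if self.n_alv != 0:
                raise ValueError("conducting airways carry no alveoli")
            for name in ("alpha0", "alpha0_prime", "n1", "n2", "A_m"):
                v = getattr(self, name)
                if v is None or v <= 0:
                    raise ValueError(f"{name} must be positive for z <= 16")
            if not 0 < self.alpha0 < 1:
                raise ValueError("alpha0 must lie in (0, 1)")
        elif self.n_alv != ALVEOLI_PER_DUCT:
            raise ValueError("acinar ducts carry 58 alveoli")

    @property
    def is_conducting(self) -> bool:
        return self.z < N_CONDUCTING


@dataclass(frozen=True)
class TreeSpec:
    """The full symmetric tree plus acinar bookkeeping constants."""

    generations: tuple[AirwayGenerationSpec, ...]
    N_a: float = TOTAL_ALVEOLI
    ducts_per_acinus: int = DUCTS_PER_ACINUS
    n_adu_total: int = N_ADU_TOTAL
    alpha_duct: float = DEFAULT_ALPHA_DUCT

    # vectorized views, filled in __post_init__
    lengths: np.ndarray = field(init=False, repr=False)
    alpha0: np.ndarray = field(init=False, repr=False)
    alpha0_prime: np.ndarray = field(init=False, repr=False)
    n1: np.ndarray = field(init=False, repr=False)
    n2: np.ndarray = field(init=False, repr=False)
    A_m: np.ndarray = field(init=False, repr=False)
    P1: np.ndarray = field(init=False, repr=False)
    P2: np.ndarray = field(init=False, repr=False)
    multiplicity: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if len(self.generations) != N_GENERATIONS:
            raise ValueError("a tree has exactly 23 generations")
        if [g.z for g in self.generations] != list(range(N_GENERATIONS)):
            raise ValueError("generations must be ordered 0..22")
        if round(self.N_a / self.n_adu_total) != ALVEOLI_PER_DUCT:
            raise ValueError("alveoli per duct must round to 58")
        if not 0 < self.alpha_duct < 1:
            raise ValueError("alpha_duct must lie in (0, 1)")
        cond = self.generations[:N_CONDUCTING]
        object.__setattr__(
            self, "lengths", np.array([g.length for g in self.generations])
        )
        object.__setattr__(self, "alpha0", np.array([g.alpha0 for g in cond]))
        object.__setattr__(
            self, "alpha0_prime", np.array([g.alpha0_prime for g in cond])
        )
        object.__setattr__(self, "n1", np.array([g.n1 for g in cond]))
        object.__setattr__(self, "n2", np.array([g.n2 for g in cond]))
        object.__setattr__(self, "A_m", np.array([g.A_m for g in cond]))
        object.__setattr__(self, "P1", self.alpha0 * self.n1 / self.alpha0_prime)
        object.__setattr__(
            self, "P2", -self.n2 * (1.0 - self.alpha0) / self.alpha0_prime
        )
        object.__setattr__(
            self, "multiplicity", 2.0 ** np.arange(N_GENERATIONS)
        )

    def reference_conducting_volume(self) -> float:
        """Conducting-airway volume (m^3) from the tabulated diameters.

        Uses the reference (metadata) diameters, not the live
        pressure-area law.
        """
        v = 0.0
        for g in self.generations[:N_CONDUCTING]:
            v += 2**g.z * np.pi * (g.ref_diameter / 2.0) ** 2 * g.length
        return float(v)


@dataclass(frozen=True)
class LungVolumes:
    """Scaling volumes of the respiratory system, in m^3."""

    TLC: float = 6.5e-3
    VC: float = 5.0e-3
    RV: float = 1.5e-3
    tidal_rest: float = 0.5e-3

    def __post_init__(self) -> None:
        if abs(self.VC - (self.TLC - self.RV)) > 1e-12:
            raise ValueError("VC must equal TLC - RV")
        if not self.RV < self.FRC < self.TLC:
            raise ValueError("FRC must lie between RV and TLC")

    @property
    def FRC(self) -> float:
        """Functional residual capacity: RV + 35% of VC."""
        return self.RV + 0.35 * self.VC


def _load_airway_table(path: str | Path | None = None) -> list[dict]:
    if path is None:
        src = resources.files("mucodyn.data") / "lambert_airways.csv"
        text = src.read_text()
    else:
        text = Path(path).read_text()
    lines = [ln for ln in text.splitlines() if ln and not ln.startswith("#")]
    return list(csv.DictReader(lines))


def build_tree_spec(
    table_path: str | Path | None = None,
    alpha_duct: float = DEFAULT_ALPHA_DUCT,
) -> TreeSpec:
    """Build the default 23-generation tree from the packaged constants.

    Parameters
    ----------
    table_path:
        Optional user override of the conducting-airway constants table
        (same CSV columns as the packaged file, printed units: cm, cm^2,
        1e-3/Pa).
    alpha_duct:
        Volume fraction of the alveolar duct lumen within an alveolar
        duct unit.
    """
    rows = _load_airway_table(table_path)
    if len(rows) != N_CONDUCTING:
        raise ValueError("airway table must have 17 conducting generations")
    gens: list[AirwayGenerationSpec] = []
    for row in rows:
        gens.append(
            AirwayGenerationSpec(
                z=int(row["z"]),
                length=float(row["l_cm"]) * 1e-2,
                ref_diameter=float(row["d_cm"]) * 1e-2,
                alpha0=float(row["alpha0"]),
                alpha0_prime=float(row["alpha0_prime_e3_per_pa"]) * 1e-3,
                n1=float(row["n1"]),
                n2=float(row["n2"]),
                A_m=float(row["Am_cm2"]) * 1e-4,
                n_alv=0,
            )
        )
    for z in range(N_CONDUCTING, N_GENERATIONS):
        gens.append(
            AirwayGenerationSpec(
                z=z,
                length=ACINAR_DUCT_LENGTH,
                ref_diameter=None,
                alpha0=None,
                alpha0_prime=None,
                n1=None,
                n2=None,
                A_m=None,
                n_alv=ALVEOLI_PER_DUCT,
            )
        )
    return TreeSpec(generations=tuple(gens), alpha_duct=alpha_duct)


def derived_alveolar_constants(
    tree: TreeSpec, vols: LungVolumes, frc_alveoli_volume: float
) -> dict:
    """Single-alveolus volume, diameter and total exchange surface.

    Alveoli are assumed spherical and identical; the exchange surface is
    the summed surface of all ``N_a`` alveoli.

    Parameters
    ----------
    frc_alveoli_volume:
        Total alveolar gas volume at the rest (FRC) state, m^3.
    """
    if frc_alveoli_volume <= 0:
        raise ValueError("alveolar volume must be positive")
    v_a = frc_alveoli_volume / tree.N_a
    diameter = (6.0 * v_a / np.pi) ** (1.0 / 3.0)
    surface = tree.N_a * np.pi * diameter**2
    return {
        "v_a": float(v_a),
        "alveolus_diameter": float(diameter),
        "exchange_surface": float(surface),
    }
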