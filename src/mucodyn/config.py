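"""Run configuration schema and result serialization.

A run is fully described by a :class:`RunConfig` (YAML or JSON on
disk).  Pressures at this boundary are cmH2O unless a key carries an
explicit ``_pa`` suffix; internal units are SI.  Unknown keys are
rejected so typos fail loudly, and the validated config is echoed into
every run manifest.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from mucodyn import constitutive
from mucodyn.dynamics import SimulationResult, StepperConfig
from mucodyn.fixtures import MucusProfile, default_mucus_profile, zero_mucus_profile
from mucodyn.maneuvers import ManeuverSpec, SessionSchedule
from mucodyn.tree_geometry import TreeSpec, build_tree_spec
from mucodyn.two_phase_flow import FluidConstants
from mucodyn.units import from_cmH2O


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class TreeConfig(_Strict):
    alpha_duct: float = Field(0.17, gt=0, lt=1)
    table_path: str | None = None


class CurvesConfig(_Strict):
    frc_transmural_pa: float = Field(500.0, gt=0)
    tlc_tissue_cmH2O: float = Field(30.0, gt=0)
    tidal_anchor_cmH2O: float = Field(5.0, gt=0)
    volume_table: str | None = None  # CSV: pressure_cmH2O, volume_L
    tissue_table: str | None = None  # CSV: volume_L, pressure_cmH2O


class FluidsConfig(_Strict):
    mu_air: float = Field(1.8e-5, gt=0)
    rho_air: float = Field(1.0, gt=0)
    sigma0: float = Field(0.1, gt=0)
    mu_mucus: float = Field(0.1, gt=0)
    rho_mucus: float = Field(1000.0, gt=0)


class SessionConfig(_Strict):
    duration_s: float = Field(230.0, gt=0)
    lead_in_s: float = Field(10.0, ge=0)
    ramp_s: float = Field(5.0, ge=0)
    tail_s: float = Field(10.0, ge=0)

    def build(self) -> SessionSchedule:
        return SessionSchedule(
            duration=self.duration_s,
            lead_in=self.lead_in_s,
            ramp_up_end=self.lead_in_s + self.ramp_s,
            ramp_down_start=self.duration_s - self.tail_s - self.ramp_s,
            tail_start=self.duration_s - self.tail_s,
        )


class ManeuverConfig(_Strict):
    family: str = "ventilation"
    P_v_cmH2O: float = Field(-5.0, le=0)
    P_cp_cmH2O: float = Field(0.0, ge=0)
    P_s_cmH2O: float = Field(0.0, ge=0)
    P_o_cmH2O: float = Field(0.0, ge=0)
    f_hz: float = Field(20.0, gt=0)
    session: SessionConfig = Field(default_factory=SessionConfig)

    def build(self) -> ManeuverSpec:
        return ManeuverSpec(
            family=self.family,
            P_v=from_cmH2O(self.P_v_cmH2O),
            P_cp=from_cmH2O(self.P_cp_cmH2O),
            P_s=from_cmH2O(self.P_s_cmH2O),
            P_o=from_cmH2O(self.P_o_cmH2O),
            f=self.f_hz,
            session=self.session.build(),
        )


class FixtureConfig(_Strict):
    preset: str = "default"  # default | zero | custom
    fill: list[float] | None = None  # 17 fractions for preset == custom
    csv_path: str | None = None

    def build(self) -> MucusProfile:
        if self.preset == "default":
            return default_mucus_profile()
        if self.preset == "zero":
            return zero_mucus_profile()
        if self.preset == "custom":
            if self.csv_path is not None:
                return MucusProfile.from_csv(Path(self.csv_path).read_text())
            if self.fill is None:
                raise ValueError("custom fixture needs 'fill' or 'csv_path'")
            return MucusProfile(fill=tuple(self.fill), name="custom")
        raise ValueError(f"unknown fixture preset {self.preset!r}")


class StepperSection(_Strict):
    dt_s: float = Field(5e-3, gt=0)
    newton_tol_pa: float = Field(1e-4, gt=0)
    r_a_floor_frac: float = Field(0.1, gt=0, lt=1)
    mucus_mode: str = "implicit"
    rigid_interface: bool = False

    def build(self) -> StepperConfig:
        return StepperConfig(
            dt=self.dt_s,
            newton_tol=self.newton_tol_pa,
            r_a_floor_frac=self.r_a_floor_frac,
            mucus_mode=self.mucus_mode,
            rigid_interface=self.rigid_interface,
        )


class OutputConfig(_Strict):
    stride: int = Field(10, ge=1)
    wide: bool = True


class RunConfig(_Strict):
    """Complete, validated description of one simulation run."""

    tree: TreeConfig = Field(default_factory=TreeConfig)
    curves: CurvesConfig = Field(default_factory=CurvesConfig)
    fluids: FluidsConfig = Field(default_factory=FluidsConfig)
    maneuver: ManeuverConfig = Field(default_factory=ManeuverConfig)
    fixture: FixtureConfig = Field(default_factory=FixtureConfig)
    stepper: StepperSection = Field(default_factory=StepperSection)
    output: OutputConfig = Field(default_factory=OutputConfig)

    @model_validator(mode="after")
    def _family_amplitudes(self):
        if self.maneuver.family == "hfcwo" and self.maneuver.P_o_cmH2O == 0 and (
            self.maneuver.P_s_cmH2O == 0
        ):
            raise ValueError("hfcwo maneuver needs P_s and/or P_o")
        return self

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        return cls.model_validate(data or {})

    def build_model(self) -> tuple[TreeSpec, "constitutive.PVCurves", FluidConstants,
                                   ManeuverSpec, MucusProfile, StepperConfig]:
        tree = build_tree_spec(
            table_path=self.tree.table_path, alpha_duct=self.tree.alpha_duct
        )
        vt = (
            np.loadtxt(self.curves.volume_table, delimiter=",")
            if self.curves.volume_table
            else None
        )
        tt = (
            np.loadtxt(self.curves.tissue_table, delimiter=",")
            if self.curves.tissue_table
            else None
        )
        curves = constitutive.build_pv_curves(
            frc_transmural_pa=self.curves.frc_transmural_pa,
            tlc_tissue_cmH2O=self.curves.tlc_tissue_cmH2O,
            tidal_anchor_cmH2O=self.curves.tidal_anchor_cmH2O,
            volume_table=vt,
            tissue_table=tt,
        )
        fluids = FluidConstants(**self.fluids.model_dump())
        return (
            tree,
            curves,
            fluids,
            self.maneuver.build(),
            self.fixture.build(),
            self.stepper.build(),
        )


# ---------------------------------------------------------------------------
# Result serialization
# ---------------------------------------------------------------------------

def _fmt(x: float) -> str:
    return f"{x:.12g}"


def tidy_frame(result: SimulationResult) -> pd.DataFrame:
    """One row per recorded time: scalars and metric traces."""
    return pd.DataFrame(
        {
            "t": result.times,
            "P_ext": result.P_ext,
            "V_L": result.V_L,
            "phi_mouth": result.phi_mouth,
            "v_out": result.v_out,
            "r": result.r,
            "R_inst": result.R_inst,
            "mmp": result.mmp,
            "iSh": result.iSh,
        }
    )


def wide_frame(result: SimulationResult) -> pd.DataFrame:
    """Per-generation mucus volumes by recorded time."""
    cols = {f"Vm_{z}": result.mucus_volumes[:, z] for z in range(17)}
    return pd.DataFrame({"t": result.times, **cols})


def summary_dict(result: SimulationResult, Com: float | None = None) -> dict:
    from mucodyn.metrics import shrek

    return {
        "v_out_final": result.final_state.v_out,
        "r_final": float(result.r[-1]),
        "mmp_initial": float(result.mmp[0]),
        "mmp_final": float(result.mmp[-1]),
        "Sh": shrek(result)["Sh"],
        "Com": Com,
        "completed": result.completed,
        "newton_iterations": result.newton_iterations,
        "occlusion_events": result.clamp_events,
        "soft_accepts": result.soft_accepts,
        "substep_events": result.substep_events,
    }


def write_outputs(
    result: SimulationResult,
    out_dir: str | Path,
    config: RunConfig | None = None,
    Com: float | None = None,
) -> None:
    """Write tidy CSV, wide CSV, summary JSON and run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tidy_frame(result).to_csv(
        out / "trace.csv", index=False, float_format="%.12g"
    )
    if config is None or config.output.wide:
        wide_frame(result).to_csv(
            out / "mucus_by_generation.csv", index=False, float_format="%.12g"
        )
    (out / "summary.json").write_text(
        json.dumps(summary_dict(result, Com), indent=2) + "\n"
    )
    manifest = {
        "config": config.model_dump() if config is not None else None,
        "curve_parameters": {
            k: float(v) for k, v in result.curves.params.items()
        },
        "completed": result.completed,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
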