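"""Study configuration schema, readers and result writers.

A study is a YAML or JSON document with explicit units (mm / N / MPa):

.. code-block:: yaml

    implants:            # [X, Y] mm, one pair per implant, labels 1..n
      - [-21.0, 17.0]
      - [-12.0, 6.0]
      - [12.0, 6.0]
      - [21.0, 17.0]
    H: 10.0              # implant length, mm
    d: 4.0               # implant diameter, mm
    nu_b: 0.35           # bone Poisson ratio
    E_b: 1000.0          # averaged bone modulus, MPa (displacements only)
    h: 0.1               # interface layer thickness, mm (displacements only)
    allow_impl: 150.0    # allowable implant stress, MPa
    allow_bone: 3.0      # allowable bone stress, MPa
    loads:               # vertical loads, N, at tooth poles (original mm)
      - {tooth: 1, Xp: 3.0, Yp: 1.0, P: 100.0}

Validation is strict and reports every violation with its field path.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from .model_core import BoneBed, ImplantArray, LoadCase
from .stress import StrengthLimits


class LoadSpec(BaseModel):
    """One vertical load case at a tooth pole (original coordinates)."""

    model_config = ConfigDict(extra="forbid")

    tooth: Optional[int] = Field(default=None, ge=1, description="tooth label 1..7")
    Xp: float = Field(description="pole X, mm")
    Yp: float = Field(description="pole Y, mm")
    P: float = Field(gt=0, description="vertical load magnitude, N")


class StudyConfig(BaseModel):
    """Validated bundle of layout, bed, limits and load cases."""

    model_config = ConfigDict(extra="forbid")

    implants: list[list[float]] = Field(min_length=3)
    H: float = Field(gt=0, description="implant length, mm")
    d: float = Field(gt=0, description="implant diameter, mm")
    nu_b: float = Field(default=0.35, ge=0, lt=0.5, description="bone Poisson ratio")
    E_b: float = Field(default=1000.0, gt=0, description="bone modulus, MPa")
    h: float = Field(default=0.1, gt=0, description="interface thickness, mm")
    allow_impl: float = Field(default=150.0, gt=0, description="allowable implant stress, MPa")
    allow_bone: float = Field(default=3.0, gt=0, description="allowable bone stress, MPa")
    loads: list[LoadSpec] = Field(min_length=1)
    grid: int = Field(default=101, ge=2, description="axial evaluation points")

    @field_validator("implants")
    @classmethod
    def _planar_pairs(cls, v: list[list[float]]) -> list[list[float]]:
        for i, p in enumerate(v):
            if len(p) != 2:
                raise ValueError(f"implant {i + 1} must be an [X, Y] pair, got {p}")
        return v

    @model_validator(mode="after")
    def _unique_teeth(self) -> "StudyConfig":
        teeth = [ld.tooth for ld in self.loads if ld.tooth is not None]
        if len(teeth) != len(set(teeth)):
            raise ValueError(f"tooth labels must be unique, got {teeth}")
        return self

    # -- converters to the analysis types -------------------------------
    def implant_array(self) -> ImplantArray:
        return ImplantArray(points=np.asarray(self.implants), H=self.H, d=self.d)

    def bone_bed(self) -> BoneBed:
        return BoneBed(nu_b=self.nu_b, E_b=self.E_b, h=self.h)

    def limits(self) -> StrengthLimits:
        return StrengthLimits(allow_impl=self.allow_impl, allow_bone=self.allow_bone)

    def load_cases(self) -> list[LoadCase]:
        return [LoadCase(P=ld.P, X_p=ld.Xp, Y_p=ld.Yp, tooth=ld.tooth) for ld in self.loads]


def load_config(path) -> StudyConfig:
    """Read and validate a YAML (``.yml``/``.yaml``) or JSON study file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    return StudyConfig.model_validate(data)


def dump_config(config: StudyConfig, path) -> None:
    """Write a study file; format chosen by extension (YAML default)."""
    path = Path(path)
    data = config.model_dump(exclude_none=True)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


# -- result writers -----------------------------------------------------

#: per-station CSV column order
PROFILE_COLUMNS = [
    "implant",
    "zeta_mm",
    "q_xi",
    "q_eta",
    "q_zeta",
    "Q_xi",
    "Q_eta",
    "Q_zeta",
    "M_xi",
    "M_eta",
    "sigma_plus",
    "sigma_minus",
    "sigma_n",
    "sigma_tau",
    "eq_impl",
    "eq_bone",
]


def profile_frame(result) -> pd.DataFrame:
    """Tidy per-implant, per-station table of a :class:`CaseResult`."""
    rows = []
    zeta = result.stresses.zeta
    for i in range(result.profile.n):
        rows.append(
            pd.DataFrame(
                {
                    "implant": i + 1,
                    "zeta_mm": zeta,
                    "q_xi": result.profile.q[i, 0],
                    "q_eta": result.profile.q[i, 1],
                    "q_zeta": result.profile.q[i, 2],
                    "Q_xi": result.actions.Q[i, 0],
                    "Q_eta": result.actions.Q[i, 1],
                    "Q_zeta": result.actions.Q[i, 2],
                    "M_xi": result.actions.M[i, 0],
                    "M_eta": result.actions.M[i, 1],
                    "sigma_plus": result.stresses.sigma_plus[i],
                    "sigma_minus": result.stresses.sigma_minus[i],
                    "sigma_n": result.stresses.sigma_n[i],
                    "sigma_tau": result.stresses.sigma_tau[i],
                    "eq_impl": result.stresses.eq_impl[i],
                    "eq_bone": result.stresses.eq_bone[i],
                }
            )
        )
    return pd.concat(rows, ignore_index=True)[PROFILE_COLUMNS]


def summary_dict(result) -> dict:
    """JSON-ready summary of one solved case (full precision)."""
    out = {
        "tooth": result.load.tooth,
        "P_N": result.load.P,
        "pole_central_mm": [float(v) for v in result.central.pole],
        "delta_mm": [float(v) for v in result.kinematics.delta],
        "theta_rad": [float(v) for v in result.kinematics.theta],
        "peak_implant_MPa": [float(v) for v in result.peaks.implant],
        "peak_bone_MPa": [float(v) for v in result.peaks.bone],
        "governing_implant": result.peaks.governing_implant,
        "governing_bone": result.peaks.governing_bone,
    }
    if result.assessment is not None:
        a = result.assessment
        out["implant_ok"] = [bool(v) for v in a.implant_ok]
        out["bone_ok"] = [bool(v) for v in a.bone_ok]
        out["implant_margin"] = [float(v) for v in a.implant_margin]
        out["bone_margin"] = [float(v) for v in a.bone_margin]
        out["ok"] = a.ok
    return out


def write_results(results, path, fmt: str = "csv") -> None:
    """Write solved cases to disk.

    ``csv`` writes the tidy per-station profile table (6 significant
    digits) for all cases, with a leading ``tooth`` column; ``json``
    writes the list of full-precision summaries.
    """
    path = Path(path)
    results = list(results)
    if fmt == "csv":
        frames = []
        for r in results:
            frame = profile_frame(r)
            frame.insert(0, "tooth", r.load.tooth)
            frames.append(frame)
        pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.6g")
    elif fmt == "json":
        path.write_text(json.dumps([summary_dict(r) for r in results], indent=2) + "\n")
    else:
        raise ValueError(f"unknown format {fmt!r}; expected 'csv' or 'json'")
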