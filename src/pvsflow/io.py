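"""Readers/writers and run configuration.

Cross-section stack format (µm everywhere, vertices counter-clockwise):

* JSON: ``{"sections": [{"z": ..., "centerline_point": [x,y,z],
  "axial_vector": [tx,ty,tz], "vertices": [[x,y], ...]}, ...]}``
* long-form CSV with columns ``section_id, z, vertex_index, x, y``.

Resistance profiles are CSV with columns
``z_um, R_local, method, A_um2, d2A_dz2`` (resistance in Pa·s/µm⁴, or in
mmHg·min/mL/m when requested).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .geometry import CrossSection, InvalidGeometryError
from .sun import ResistanceProfile

#: Pa·s/µm⁴ -> mmHg·min/mL/m, from 1 mmHg = 133.322 Pa, 1 min = 60 s,
#: 1 mL = 1e12 µm³, 1 m = 1e6 µm
PA_S_PER_UM4_TO_MMHG_MIN_PER_ML_PER_M = 1e18 / (133.322 * 60.0)

UNIT_TAGS = ("SI-um", "mmHg-min-mL-m")


def unit_factor(units: str) -> float:
    if units == "SI-um":
        return 1.0
    if units == "mmHg-min-mL-m":
        return PA_S_PER_UM4_TO_MMHG_MIN_PER_ML_PER_M
    raise ValueError(f"unknown units tag {units!r}; expected one of {UNIT_TAGS}")


def write_stack(sections: list[CrossSection], path: str | Path) -> None:
    """Write a cross-section stack as JSON (or long CSV for .csv paths)."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        rows = []
        for sid, s in enumerate(sections):
            for vi, (x, y) in enumerate(s.vertices):
                rows.append((sid, s.z, vi, x, y))
        pd.DataFrame(
            rows, columns=["section_id", "z", "vertex_index", "x", "y"]
        ).to_csv(path, index=False)
        return
    payload = {
        "sections": [
            {
                "z": s.z,
                "centerline_point": list(map(float, s.centerline_point)),
                "axial_vector": list(map(float, s.axial_vector)),
                "vertices": s.vertices.tolist(),
            }
            for s in sections
        ]
    }
    path.write_text(json.dumps(payload))


def read_stack(path: str | Path) -> list[CrossSection]:
    """Read a stack file (JSON or long CSV); validates ordering and polygons."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sections: list[CrossSection] = []
    if path.suffix.lower() == ".csv":
        df = pd.read_csv(path)
        need = {"section_id", "z", "vertex_index", "x", "y"}
        if not need.issubset(df.columns):
            raise ValueError(
                f"{path}: CSV stack needs columns {sorted(need)}, "
                f"found {list(df.columns)}"
            )
        for sid, grp in df.groupby("section_id", sort=True):
            grp = grp.sort_values("vertex_index")
            try:
                sections.append(
                    CrossSection(
                        z=float(grp["z"].iloc[0]),
                        vertices=grp[["x", "y"]].to_numpy(),
                    )
                )
            except InvalidGeometryError as exc:
                raise InvalidGeometryError(f"{path}: section {sid}: {exc}") from exc
    else:
        data = json.loads(path.read_text())
        for i, rec in enumerate(data["sections"]):
            try:
                sections.append(
                    CrossSection(
                        z=float(rec["z"]),
                        vertices=np.asarray(rec["vertices"], float),
                        axial_vector=np.asarray(
                            rec.get("axial_vector", [0, 0, 1]), float
                        ),
                        centerline_point=np.asarray(
                            rec.get("centerline_point", [0, 0, rec["z"]]), float
                        ),
                    )
                )
            except (InvalidGeometryError, KeyError) as exc:
                raise InvalidGeometryError(f"{path}: section {i}: {exc}") from exc
    zs = [s.z for s in sections]
    for i in range(1, len(zs)):
        if zs[i] <= zs[i - 1]:
            raise InvalidGeometryError(
                f"{path}: z not strictly increasing at section {i} "
                f"(z={zs[i]} after z={zs[i - 1]})"
            )
    return sections


def write_profile(
    profile: ResistanceProfile, path: str | Path, units: str = "SI-um"
) -> None:
    """Write a resistance profile to CSV, applying the unit conversion."""
    f = unit_factor(units)
    df = pd.DataFrame(
        {
            "z_um": profile.z,
            "R_local": profile.R_local * f,
            "method": profile.method,
            "A_um2": profile.A_um2 if profile.A_um2 is not None else np.nan,
            "d2A_dz2": (
                profile.d2A_dz2 if profile.d2A_dz2 is not None else np.nan
            ),
        }
    )
    df.attrs["units"] = units
    with open(path, "w") as fh:
        fh.write(f"# units={units}\n")
        df.to_csv(fh, index=False, float_format="%.12e")


def read_profile(path: str | Path) -> tuple[ResistanceProfile, str]:
    """Read a profile CSV; returns (profile in Pa·s/µm⁴, units tag found)."""
    with open(path) as fh:
        first = fh.readline()
        units = "SI-um"
        if first.startswith("# units="):
            units = first.strip().split("=", 1)[1]
            df = pd.read_csv(fh)
        else:
            fh.seek(0)
            df = pd.read_csv(fh)
    f = unit_factor(units)
    return (
        ResistanceProfile(
            z=df["z_um"].to_numpy(),
            R_local=df["R_local"].to_numpy() / f,
            method=str(df["method"].iloc[0]),
            A_um2=df["A_um2"].to_numpy() if "A_um2" in df else None,
            d2A_dz2=df["d2A_dz2"].to_numpy() if "d2A_dz2" in df else None,
        ),
        units,
    )


@dataclass
class RunConfig:
    """Bundle of physical and numerical parameters for CLI runs."""

    mu: float = 6.9e-4
    Q: float = 2.19e4
    resample_dz: float = 0.7
    mesh_size: float | None = None
    N_boundary: int = 100
    correction_model: str = "analytic"
    units: str = "SI-um"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.mu <= 0 or self.Q <= 0 or self.resample_dz <= 0:
            raise ValueError("physical parameters must be positive")
        if self.units not in UNIT_TAGS:
            raise ValueError(f"units must be one of {UNIT_TAGS}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]


def error_table(
    test: ResistanceProfile, reference: ResistanceProfile
) -> pd.DataFrame:
    """Per-station signed percent error of ``test`` against ``reference``.

    The percentage base is the reference value, matching the convention of
    comparing approximate profiles against a trusted solution.
    """
    if len(test.z) != len(reference.z) or not np.allclose(test.z, reference.z):
        raise ValueError("profiles must share the same stations")
    err = 100.0 * (test.R_local - reference.R_local) / reference.R_local
    return pd.DataFrame(
        {
            "z_um": test.z,
            "R_test": test.R_local,
            "R_ref": reference.R_local,
            "err_percent": err,
        }
    )


def error_summary(table: pd.DataFrame, valid=None) -> dict:
    err = table["err_percent"].to_numpy()
    if valid is not None:
        err = err[np.asarray(valid, bool)]
    return {
        "avg_percent": float(np.mean(err)),
        "rms_percent": float(np.sqrt(np.mean(err**2))),
    }
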