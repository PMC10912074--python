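"""File formats: TAC/blood-table CSV, NIfTI volumes, fit JSON, YAML specs.

CSV round trips preserve full double precision (17 significant digits);
volume round trips are bit-exact.  Times are minutes, activities kBq/mL,
dose MBq, weight kg throughout; SUV is g/mL (the kg->g and MBq->kBq
factors of 1000 cancel, see :mod:`fespet.visibility`).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .image import DynamicImage
from .kinetics import FitResult, KineticParams
from .patlak import ParametricImage
from .phantom import (
    BloodSampleTable,
    Cylinder,
    Ellipsoid,
    PhantomSpec,
    Region,
    Sphere,
)
from .schedule import FrameSchedule
from .tac import TimeActivityCurve

__all__ = [
    "read_tac",
    "write_tac",
    "read_blood_table",
    "write_blood_table",
    "read_dynamic",
    "write_dynamic",
    "read_volume",
    "write_volume",
    "write_mask",
    "read_mask",
    "write_parametric",
    "write_fit_json",
    "read_fit_json",
    "write_input_csv",
    "read_input_csv",
    "write_phantom_spec",
    "read_phantom_spec",
    "provenance_block",
]

_FLOAT_FMT = "%.17g"


class ParseError(ValueError):
    pass


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {', '.join(missing)}")


# ---------------------------------------------------------------- TAC CSV


def write_tac(tac: TimeActivityCurve, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "time_min": tac.mid_times,
            "duration_min": tac.durations,
            "activity_kBq_mL": tac.activity,
        }
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_tac(path: str | Path, label: str | None = None) -> TimeActivityCurve:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["time_min", "duration_min", "activity_kBq_mL"], path)
    return TimeActivityCurve(
        mid_times=df["time_min"].to_numpy(),
        durations=df["duration_min"].to_numpy(),
        activity=df["activity_kBq_mL"].to_numpy(),
        label=label,
    )


# ------------------------------------------------------- blood table CSV

_BLOOD_COLS = ["time_min", "whole_blood_kBq_mL", "plasma_kBq_mL", "parent_fraction"]


def write_blood_table(table: BloodSampleTable, path: str | Path) -> None:
    df = pd.DataFrame(
        dict(
            zip(
                _BLOOD_COLS,
                [table.time_min, table.whole_blood, table.plasma, table.parent_fraction],
            )
        )
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_blood_table(path: str | Path) -> BloodSampleTable:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, _BLOOD_COLS, path)
    return BloodSampleTable(
        time_min=df["time_min"].to_numpy(),
        whole_blood=df["whole_blood_kBq_mL"].to_numpy(),
        plasma=df["plasma_kBq_mL"].to_numpy(),
        parent_fraction=df["parent_fraction"].to_numpy(),
    )


# ---------------------------------------------------------- input CSV


def write_input_csv(inp, times: np.ndarray, path: str | Path) -> None:
    """Tabulate a corrected input function at the given times."""
    times = np.asarray(times, dtype=float)
    df = pd.DataFrame(
        {
            "time_min": times,
            "Cwb_kBq_mL": np.asarray(inp.whole_blood(times)),
            "Cp_parent_kBq_mL": np.asarray(inp.parent_plasma(times)),
        }
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_input_csv(path: str | Path):
    """Read a tabulated input back as an InputFunctionSet-compatible object.

    Whole blood and parent plasma are interpolated piecewise linearly with
    (0, 0) prepended when absent and constant extrapolation at the end.
    """
    from .input_function import InputFunctionSet

    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["time_min", "Cwb_kBq_mL", "Cp_parent_kBq_mL"], path)
    t = df["time_min"].to_numpy(dtype=float)
    wb = df["Cwb_kBq_mL"].to_numpy(dtype=float)
    cp = df["Cp_parent_kBq_mL"].to_numpy(dtype=float)
    if t[0] > 0:
        t = np.concatenate([[0.0], t])
        wb = np.concatenate([[0.0], wb])
        cp = np.concatenate([[0.0], cp])

    wb_f = lambda x: np.interp(np.asarray(x, dtype=float), t, wb)
    with np.errstate(divide="ignore", invalid="ignore"):
        pf_ratio = np.where(wb > 0, cp / wb, 1.0)

    class _TabulatedPF:
        def __call__(self, x):
            return np.interp(np.asarray(x, dtype=float), t, pf_ratio)

    # p2wb ratio folded into the tabulated Cp/Cwb ratio; report 1.0
    return InputFunctionSet(whole_blood=wb_f, p2wb_ratio=1.0, parent_fraction=_TabulatedPF())


# ---------------------------------------------------------- NIfTI volumes


def _affine(voxel_size_mm) -> np.ndarray:
    aff = np.diag(list(voxel_size_mm) + [1.0])
    return aff


def write_volume(
    data: np.ndarray, voxel_size_mm, path: str | Path, descrip: str = ""
) -> None:
    img = nib.Nifti1Image(np.asarray(data), _affine(voxel_size_mm))
    img.header["pixdim"][1:4] = voxel_size_mm
    if descrip:
        img.header["descrip"] = descrip.encode()[:79]
    nib.save(img, str(path))


def read_volume(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    vox = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.dataobj), vox


def write_mask(mask: np.ndarray, voxel_size_mm, path: str | Path) -> None:
    write_volume(mask.astype(np.uint8), voxel_size_mm, path, descrip="binary mask")


def read_mask(path: str | Path) -> np.ndarray:
    data, _ = read_volume(path)
    return data.astype(bool)


def write_dynamic(img: DynamicImage, path: str | Path) -> None:
    """4D volume plus a JSON frame-schedule sidecar (<path>.frames.json)."""
    write_volume(img.data, img.voxel_size_mm, path, descrip="dynamic PET kBq/mL")
    side = {
        "frames": [list(f) for f in img.schedule.frames],
        "pass_labels": list(img.schedule.pass_labels) if img.schedule.pass_labels else None,
    }
    Path(str(path) + ".frames.json").write_text(json.dumps(side))


def read_dynamic(path: str | Path) -> DynamicImage:
    data, vox = read_volume(path)
    side_path = Path(str(path) + ".frames.json")
    if not side_path.exists():
        raise FileNotFoundError(f"frame schedule sidecar not found: {side_path}")
    side = json.loads(side_path.read_text())
    sch = FrameSchedule(
        tuple(tuple(f) for f in side["frames"]),
        tuple(side["pass_labels"]) if side.get("pass_labels") else None,
    )
    return DynamicImage(data=data, voxel_size_mm=vox, schedule=sch)


def write_parametric(par: ParametricImage, stem: str | Path) -> dict[str, Path]:
    """Write Ki, V and r² volumes as <stem>_ki/_v/_r2.nii.gz."""
    stem = Path(stem)
    out = {}
    for name, vol, unit in (
        ("ki", par.ki, "Ki mL/cm^3/min"),
        ("v", par.v, "V mL/cm^3"),
        ("r2", par.r_squared, "r^2"),
    ):
        p = stem.parent / f"{stem.name}_{name}.nii.gz"
        write_volume(vol, par.voxel_size_mm, p, descrip=f"{unit}; t*={par.t_star} min")
        out[name] = p
    return out


# ------------------------------------------------------------- fit JSON


def write_fit_json(fits: FitResult | list[FitResult] | dict, path: str | Path, provenance: dict | None = None) -> None:
    if isinstance(fits, FitResult):
        payload = fits.to_dict()
    elif isinstance(fits, list):
        payload = [f.to_dict() for f in fits]
    else:
        payload = {
            k: (v.to_dict() if isinstance(v, FitResult) else v) for k, v in fits.items()
        }
    doc = {"fits": payload}
    if provenance:
        doc["provenance"] = provenance
    Path(path).write_text(json.dumps(doc, indent=2))


def read_fit_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


# ------------------------------------------------------- phantom spec YAML


def _shape_to_dict(shape) -> dict:
    if isinstance(shape, Sphere):
        return {"type": "sphere", "center_mm": list(shape.center_mm), "diameter_mm": shape.diameter_mm}
    if isinstance(shape, Ellipsoid):
        return {"type": "ellipsoid", "center_mm": list(shape.center_mm), "radii_mm": list(shape.radii_mm)}
    if isinstance(shape, Cylinder):
        return {
            "type": "cylinder",
            "center_xy_mm": list(shape.center_xy_mm),
            "radius_mm": shape.radius_mm,
            "z_range_mm": list(shape.z_range_mm),
        }
    raise TypeError(f"unknown shape {shape!r}")


def _shape_from_dict(d: dict):
    kind = d.get("type")
    if kind == "sphere":
        return Sphere(tuple(d["center_mm"]), d["diameter_mm"])
    if kind == "ellipsoid":
        return Ellipsoid(tuple(d["center_mm"]), tuple(d["radii_mm"]))
    if kind == "cylinder":
        return Cylinder(tuple(d["center_xy_mm"]), d["radius_mm"], tuple(d["z_range_mm"]))
    raise ParseError(f"unknown shape type {kind!r}")


def _region_to_dict(reg: Region) -> dict:
    d = {"name": reg.name, "shape": _shape_to_dict(reg.shape)}
    if reg.kinetics is not None:
        d["kinetics"] = {k: float(v) for k, v in dataclasses.asdict(reg.kinetics).items()}
    else:
        d["tac"] = [float(v) for v in reg.tac]
    return d


def _region_from_dict(d: dict) -> Region:
    kin = d.get("kinetics")
    return Region(
        name=d["name"],
        shape=_shape_from_dict(d["shape"]),
        kinetics=KineticParams(**kin) if kin is not None else None,
        tac=np.asarray(d["tac"], dtype=float) if "tac" in d else None,
    )


def write_phantom_spec(spec: PhantomSpec, path: str | Path) -> None:
    doc = {
        "grid_shape": list(spec.grid_shape),
        "voxel_size_mm": list(spec.voxel_size_mm),
        "organs": [_region_to_dict(r) for r in spec.organs],
        "lesions": [_region_to_dict(r) for r in spec.lesions],
        "injected_dose_mbq": spec.injected_dose_mbq,
        "body_weight_kg": spec.body_weight_kg,
        "psf_fwhm_mm": spec.psf_fwhm_mm,
        "noise_coefficient": spec.noise_coefficient,
        "seed": spec.seed,
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_phantom_spec(path: str | Path) -> PhantomSpec:
    doc = yaml.safe_load(Path(path).read_text())
    return PhantomSpec(
        grid_shape=tuple(doc["grid_shape"]),
        voxel_size_mm=tuple(doc["voxel_size_mm"]),
        organs=[_region_from_dict(r) for r in doc["organs"]],
        lesions=[_region_from_dict(r) for r in doc["lesions"]],
        injected_dose_mbq=doc["injected_dose_mbq"],
        body_weight_kg=doc["body_weight_kg"],
        psf_fwhm_mm=doc["psf_fwhm_mm"],
        noise_coefficient=doc["noise_coefficient"],
        seed=doc["seed"],
    )


# ------------------------------------------------------------ provenance


def provenance_block(config: dict, seed: int) -> dict:
    """Provenance attached to every pipeline artifact."""
    from . import __version__

    canonical = json.dumps(config, sort_keys=True, default=str)
    return {
        "config_sha256": hashlib.sha256(canonical.encode()).hexdigest(),
        "seed": int(seed),
        "package_version": __version__,
    }
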