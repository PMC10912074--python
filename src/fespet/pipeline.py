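"""End-to-end orchestration: simulate -> blood -> fit -> patlak -> suv ->
visibility -> report.

Each stage writes its artifacts plus a ``<stage>.provenance.json`` block
(config hash, seed, package version).  Re-running a stage whose provenance
matches the current configuration is a no-op, so a pipeline can be resumed
stage by stage.  All randomness derives from the single configured seed.
"""

from __future__ import annotations

import json
import logging
import time as _time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as fio
from .blood import correct_input, extract_idif, fit_metabolite_correction
from .input_function import make_input_function
from .kinetics import ModelContext, compare_models, fit_2tcm
from .patlak import patlak_fit, patlak_image, patlak_points
from .phantom import build_phantom, default_phantom_spec, sample_blood
from .schedule import default_schedule
from .tac import TimeActivityCurve
from .visibility import (
    background_shell,
    compare_image_types,
    isocontour_voi,
    lesion_stats,
    screen_lesions,
    suv_image,
)

__all__ = ["PipelineConfig", "run_pipeline", "StageError"]

log = logging.getLogger("fespet.pipeline")

STAGES = ("simulate", "blood", "fit", "patlak", "suv", "visibility", "report")


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    out_dir: str = "fespet_out"
    phantom_spec_path: str | None = None  # None -> built-in default phantom
    seed: int = 0
    noise_coefficient: float | None = None  # None -> spec default
    psf_fwhm_mm: float | None = None
    fit_mode: str = "both"  # irreversible | reversible | both
    fit_weights: str | None = None  # None (uniform) | "duration"
    patlak_t_star: float = 40.0
    patlak_t_max: float = 70.0
    suv_window: tuple[float, float] = (60.0, 70.0)
    lesion_suvmax_threshold: float = 1.5

    def to_dict(self) -> dict:
        d = asdict(self)
        d["suv_window"] = list(self.suv_window)
        return d


def _stage_done(out: Path, stage: str, prov: dict) -> bool:
    p = out / f"{stage}.provenance.json"
    if not p.exists():
        return False
    try:
        return json.loads(p.read_text()) == prov
    except (json.JSONDecodeError, OSError):
        return False


def _mark_done(out: Path, stage: str, prov: dict) -> None:
    (out / f"{stage}.provenance.json").write_text(json.dumps(prov, indent=2))


def run_pipeline(config: PipelineConfig, stages: tuple[str, ...] = STAGES) -> dict:
    """Execute the pipeline; returns the report dictionary.

    Stage artifacts land in ``config.out_dir``.  Failures are re-raised as
    :class:`StageError` carrying the stage name.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prov = fio.provenance_block(config.to_dict(), config.seed)

    inp = make_input_function()
    schedule = default_schedule()
    ctx = ModelContext(inp, schedule)

    if config.phantom_spec_path is not None:
        spec_path = Path(config.phantom_spec_path)
        if not spec_path.exists():
            raise StageError("simulate", f"phantom spec file not found: {spec_path}")
        spec = fio.read_phantom_spec(spec_path)
    else:
        spec = default_phantom_spec(inp, schedule)
    if config.noise_coefficient is not None:
        spec.noise_coefficient = config.noise_coefficient
    if config.psf_fwhm_mm is not None:
        spec.psf_fwhm_mm = config.psf_fwhm_mm
    spec.seed = config.seed

    report: dict = {"config": config.to_dict(), "provenance": prov, "stages": {}}

    def _run(stage, fn):
        if stage not in stages:
            return
        t0 = _time.time()
        if _stage_done(out, stage, prov):
            log.info("stage %s: up to date, skipping", stage)
            return
        try:
            fn()
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001 - annotate stage context
            raise StageError(stage, str(exc)) from exc
        _mark_done(out, stage, prov)
        log.info("stage %s: %.1f s", stage, _time.time() - t0)

    # ---- simulate ----------------------------------------------------
    def simulate():
        img, masks = build_phantom(spec, inp, schedule, context=ctx)
        fio.write_dynamic(img, out / "dynamic.nii")
        labels = np.zeros(spec.grid_shape, dtype=np.int16)
        names = {}
        for i, (name, m) in enumerate(masks.items(), start=1):
            labels[m] = i
            names[i] = name
        fio.write_volume(labels, spec.voxel_size_mm, out / "regions.nii", "region labels")
        (out / "regions.json").write_text(json.dumps(names))
        fio.write_phantom_spec(spec, out / "phantom_spec.yaml")
        table = sample_blood(inp, seed=config.seed + 1)
        fio.write_blood_table(table, out / "blood_samples.csv")

    _run("simulate", simulate)
    if not (out / "dynamic.nii").exists():
        return report

    img = fio.read_dynamic(out / "dynamic.nii")
    labels, _ = fio.read_volume(out / "regions.nii")
    names = {int(k): v for k, v in json.loads((out / "regions.json").read_text()).items()}
    masks = {name: labels == i for i, name in names.items()}
    spec = fio.read_phantom_spec(out / "phantom_spec.yaml")

    # ---- blood -------------------------------------------------------
    def blood():
        idif = extract_idif(img, masks["aorta"])
        fio.write_tac(idif, out / "idif.csv")
        table = fio.read_blood_table(out / "blood_samples.csv")
        corr = fit_metabolite_correction(table)
        cin = correct_input(idif, corr)
        fio.write_input_csv(cin, img.schedule.mid_times, out / "input_corrected.csv")
        (out / "metabolite_fit.json").write_text(
            json.dumps(
                {
                    "p2wb_ratio": corr.p2wb_ratio,
                    "parent_fraction": {
                        "t50": corr.parent_fraction.t50,
                        "hill_n": corr.parent_fraction.hill_n,
                        "floor_b": corr.parent_fraction.floor_b,
                    },
                    "pf_residual_rms": corr.pf_residual_rms,
                },
                indent=2,
            )
        )

    _run("blood", blood)

    idif = fio.read_tac(out / "idif.csv", label="IDIF")
    corr = fit_metabolite_correction(fio.read_blood_table(out / "blood_samples.csv"))
    input_used = correct_input(idif, corr)
    fit_ctx = ModelContext(input_used, img.schedule)

    region_tacs = {
        name: TimeActivityCurve(
            mid_times=img.schedule.mid_times,
            durations=img.schedule.durations,
            activity=img.data[mask].mean(axis=0),
            label=name,
        )
        for name, mask in masks.items()
        if mask.any() and name != "aorta"
    }

    # ---- fit ---------------------------------------------------------
    def fit():
        rows = []
        fits = {}
        for name, tac in region_tacs.items():
            entry = {}
            if config.fit_mode in ("irreversible", "both"):
                entry["irreversible"] = fit_2tcm(
                    tac, input_used, img.schedule, "irreversible",
                    weights=config.fit_weights, seed=config.seed, context=fit_ctx,
                )
            if config.fit_mode in ("reversible", "both"):
                entry["reversible"] = fit_2tcm(
                    tac, input_used, img.schedule, "reversible",
                    weights=config.fit_weights, seed=config.seed, context=fit_ctx,
                )
            fits[name] = entry
            row = {"region": name}
            if "irreversible" in entry:
                fi = entry["irreversible"]
                row.update(ki_2tcm=fi.ki, aic_irr=fi.aic, K1=fi.params.K1)
            if len(entry) == 2:
                cmp_ = compare_models(entry["reversible"], entry["irreversible"])
                row.update(
                    aic_rev=entry["reversible"].aic,
                    delta_aic=cmp_.delta_aic,
                    preferred=cmp_.preferred,
                    significant=cmp_.significant,
                )
            rows.append(row)
        pd.DataFrame(rows).to_csv(out / "fits_summary.csv", index=False, float_format="%.6g")
        fio.write_fit_json(
            {n: {m: f.to_dict() for m, f in e.items()} for n, e in fits.items()},
            out / "fits.json",
            provenance=prov,
        )

    _run("fit", fit)

    # ---- patlak ------------------------------------------------------
    def patlak():
        par = patlak_image(img, input_used, t_star=config.patlak_t_star, t_max=config.patlak_t_max)
        fio.write_parametric(par, out / "patlak")
        # regional Patlak vs full 2TCM Ki (irreversible) for lesions
        rows = []
        fits_doc = json.loads((out / "fits.json").read_text()) if (out / "fits.json").exists() else None
        for name, tac in region_tacs.items():
            pf = patlak_fit(
                patlak_points(tac, input_used),
                t_star=config.patlak_t_star,
                t_max=config.patlak_t_max,
            )
            row = {"region": name, "ki_patlak": pf.ki, "v_patlak": pf.v, "r2": pf.r_squared}
            if fits_doc and name in fits_doc["fits"] and "irreversible" in fits_doc["fits"][name]:
                row["ki_2tcm"] = fits_doc["fits"][name]["irreversible"]["ki"]
            rows.append(row)
        pd.DataFrame(rows).to_csv(out / "patlak_regions.csv", index=False, float_format="%.6g")

    _run("patlak", patlak)

    # ---- suv ---------------------------------------------------------
    def suv():
        s = suv_image(img, spec.injected_dose_mbq, spec.body_weight_kg, config.suv_window)
        fio.write_volume(s.data, s.voxel_size_mm, out / "suv.nii", "SUV g/mL (bw)")

    _run("suv", suv)

    # ---- visibility --------------------------------------------------
    def visibility():
        suv_data, vox = fio.read_volume(out / "suv.nii")
        ki_data, _ = fio.read_volume(out / "patlak_ki.nii.gz")
        lesion_masks = {n: m for n, m in masks.items() if n.startswith("lesion")}
        host = np.zeros(img.data.shape[:3], dtype=bool)
        for n, m in masks.items():
            if not n.startswith("lesion") and n != "aorta":
                host |= m

        class _SUV:  # minimal shim: screen_lesions needs .data only
            data = suv_data

        recs = screen_lesions(_SUV, lesion_masks, threshold=config.lesion_suvmax_threshold)
        rows, pairs_tbr, pairs_cnr = [], [], []
        for rec in recs:
            lesion = lesion_masks[rec.lesion_id]
            bg = background_shell(lesion, host)
            row = {
                "lesion_id": rec.lesion_id,
                "suv_max": rec.suv_max,
                "suv_mean": rec.suv_mean,
                "included": rec.included,
            }
            if rec.included and bg.any():
                voi = isocontour_voi(suv_data, lesion)
                tbr_s, cnr_s = lesion_stats(suv_data, voi, bg)
                tbr_k, cnr_k = lesion_stats(ki_data, voi, bg)
                row.update(tbr_suv=tbr_s, cnr_suv=cnr_s, tbr_ki=tbr_k, cnr_ki=cnr_k)
                pairs_tbr.append((tbr_s, tbr_k))
                pairs_cnr.append((cnr_s, cnr_k))
            rows.append(row)
        pd.DataFrame(rows).to_csv(out / "visibility.csv", index=False, float_format="%.6g")
        summary = {"n_included": len(pairs_tbr)}
        if len(pairs_tbr) >= 2 and all(v > 0 for p in pairs_tbr for v in p):
            c = compare_image_types(pairs_tbr)
            summary["tbr"] = {
                "ratio": c.ratio, "ci": [c.ci_low, c.ci_high],
                "p_value": c.p_value, "n_ki_higher": c.n_higher, "n_pairs": c.n_pairs,
            }
        if len(pairs_cnr) >= 2 and all(v > 0 for p in pairs_cnr for v in p):
            c = compare_image_types(pairs_cnr)
            summary["cnr"] = {
                "ratio": c.ratio, "ci": [c.ci_low, c.ci_high],
                "p_value": c.p_value, "n_ki_higher": c.n_higher, "n_pairs": c.n_pairs,
            }
        (out / "visibility_summary.json").write_text(json.dumps(summary, indent=2))

    _run("visibility", visibility)

    # ---- report ------------------------------------------------------
    def report_stage():
        doc = {"provenance": prov}
        for name, path in [
            ("fits", "fits_summary.csv"),
            ("patlak_regions", "patlak_regions.csv"),
            ("visibility", "visibility.csv"),
        ]:
            p = out / path
            if p.exists():
                doc[name] = pd.read_csv(p).to_dict(orient="records")
        vs = out / "visibility_summary.json"
        if vs.exists():
            doc["visibility_summary"] = json.loads(vs.read_text())
        mf = out / "metabolite_fit.json"
        if mf.exists():
            doc["metabolite_fit"] = json.loads(mf.read_text())
        (out / "report.json").write_text(json.dumps(doc, indent=2, default=float))

    _run("report", report_stage)
    if (out / "report.json").exists():
        report["report"] = json.loads((out / "report.json").read_text())
    return report
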