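"""Image-derived input function (IDIF) and metabolite correction.

The whole-blood input is extracted from a volume of interest in the
descending aorta of the dynamic image; venous blood samples provide the
plasma-to-whole-blood ratio and the parent-fraction time course, which
convert the IDIF into the metabolite-corrected parent-plasma input the
kinetic models require.  Venous and arterial concentrations are assumed
equivalent after the first ~2 min; no dispersion or partial-volume
correction is applied (a PSF-blurred aorta therefore yields a known
underestimate of the early peak).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .image import DynamicImage
from .input_function import InputFunctionSet, ParentFractionModel
from .phantom import BloodSampleTable
from .tac import TimeActivityCurve

__all__ = [
    "MetaboliteCorrection",
    "extract_idif",
    "fit_metabolite_correction",
    "correct_input",
]


@dataclass
class MetaboliteCorrection:
    """Fitted parent-fraction model plus the plasma-to-whole-blood ratio.

    ``p2wb_ratio`` is the mean of the per-sample plasma/whole-blood ratios
    (the ratio is constant in time for [18F]FES); ``pf_residual_rms``
    reports the parent-fraction fit quality.
    """

    parent_fraction: ParentFractionModel
    p2wb_ratio: float
    pf_residuals: np.ndarray
    ratio_residuals: np.ndarray

    def __post_init__(self) -> None:
        if self.p2wb_ratio <= 0:
            raise ValueError("p2wb_ratio must be positive")

    @property
    def pf_residual_rms(self) -> float:
        return float(np.sqrt(np.mean(self.pf_residuals**2)))


def extract_idif(img: DynamicImage, aorta_mask: np.ndarray) -> TimeActivityCurve:
    """Whole-blood TAC: per-frame mean over the aorta VOI voxels."""
    mask = np.asarray(aorta_mask, dtype=bool)
    if mask.shape != img.data.shape[:3]:
        raise ValueError(
            f"mask shape {mask.shape} does not match image {img.data.shape[:3]}"
        )
    if not mask.any():
        raise ValueError("aorta mask is empty")
    vals = img.data[mask].mean(axis=0)
    return TimeActivityCurve(
        mid_times=img.schedule.mid_times,
        durations=img.schedule.durations,
        activity=vals,
        label="IDIF",
    )


def fit_metabolite_correction(samples: BloodSampleTable) -> MetaboliteCorrection:
    """Least-squares fit of the parent-fraction model to measured samples.

    The plasma-to-whole-blood ratio is estimated as the mean of the
    per-sample plasma/whole-blood ratios.  Requires at least three samples.

    An all-parent limit (every measured fraction 1) is represented by the
    floor of the sigmoid approaching 1, so pf stays ~1 at all times.
    """
    if len(samples) < 3:
        raise ValueError("need at least 3 blood samples")
    t = samples.time_min
    pf_meas = samples.parent_fraction
    if np.any(samples.whole_blood <= 0):
        raise ValueError("whole-blood activities must be positive")
    ratios = samples.plasma / samples.whole_blood
    ratio = float(np.mean(ratios))

    def residual(theta: np.ndarray) -> np.ndarray:
        m = ParentFractionModel(theta[0], theta[1], min(theta[2], 1.0 - 1e-12))
        return m(t) - pf_meas

    lo = [1e-6, 1e-6, 0.0]
    hi = [1e4, 20.0, 1.0 - 1e-9]
    best = None
    for x0 in ([10.0, 1.0, 0.1], [30.0, 0.7, 0.0], [5.0, 2.0, 0.3]):
        sol = least_squares(residual, x0, bounds=(lo, hi), xtol=1e-14, ftol=1e-14)
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not np.all(np.isfinite(best.x)):
        raise RuntimeError(
            f"parent-fraction fit did not converge; residuals {residual(best.x) if best else None}"
        )
    model = ParentFractionModel(best.x[0], best.x[1], min(best.x[2], 1.0 - 1e-12))
    return MetaboliteCorrection(
        parent_fraction=model,
        p2wb_ratio=ratio,
        pf_residuals=residual(best.x),
        ratio_residuals=ratios - ratio,
    )


class _InterpolatedCurve:
    """Piecewise-linear whole-blood curve from a frame-sampled TAC.

    (0, 0) is prepended (activity starts at zero at injection) and the last
    value is extrapolated as a constant beyond the final mid-time.
    """

    def __init__(self, tac: TimeActivityCurve, delay_min: float = 0.0):
        self.t = np.concatenate([[0.0], tac.mid_times + delay_min])
        self.v = np.concatenate([[0.0], tac.activity])
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("delay produces non-increasing knots")

    def __call__(self, t: np.ndarray | float) -> np.ndarray | float:
        t = np.asarray(t, dtype=float)
        out = np.interp(t, self.t, self.v)
        return out if out.ndim else float(out)


def correct_input(
    idif: TimeActivityCurve,
    corr: MetaboliteCorrection,
    delay_min: float = 0.0,
) -> InputFunctionSet:
    """Combine an IDIF with the metabolite correction into an input set.

    The whole-blood curve is the piecewise-linear interpolation of the IDIF
    with (0, 0) prepended and constant extrapolation beyond the last frame;
    the parent-plasma curve is Cp(t) = Cwb(t) * R * pf(t).  ``delay_min``
    shifts the IDIF (default 0; no dispersion modelling).
    """
    return InputFunctionSet(
        whole_blood=_InterpolatedCurve(idif, delay_min),
        p2wb_ratio=corr.p2wb_ratio,
        parent_fraction=corr.parent_fraction,
    )
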