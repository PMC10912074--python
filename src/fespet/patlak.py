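"""Patlak graphical analysis and voxelwise parametric Ki/V imaging.

For irreversible tracer uptake the transformed coordinates

    x(t) = int_0^t Cp(s) ds / Cp(t)      ("normalised time")
    y(t) = C(t) / Cp(t)

become linear after an equilibration time t*; the slope is the net influx
rate Ki and the intercept V is the distribution volume of free tracer in
blood and reversible compartments.  The default fit window is 40-70 min
(the last six 5-min whole-body passes of the first scan session).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .input_function import InputFunctionSet
from .tac import TimeActivityCurve

__all__ = ["PatlakFit", "ParametricImage", "patlak_points", "patlak_fit", "patlak_image"]


@dataclass(frozen=True)
class PatlakFit:
    """Ordinary least-squares Patlak line over frames with mid-time >= t_star."""

    ki: float  # slope [mL·cm⁻³·min⁻¹]
    v: float  # intercept [mL·cm⁻³]
    t_star: float
    n_points: int
    r_squared: float


@dataclass
class ParametricImage:
    """Voxelwise Ki, V and r² maps with provenance."""

    ki: np.ndarray
    v: np.ndarray
    r_squared: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    t_star: float
    t_max: float | None = None


def patlak_points(
    tac: TimeActivityCurve, inp: InputFunctionSet
) -> list[tuple[float, float, float]]:
    """Patlak coordinates ``(x, y, mid_time)`` at the TAC's frame mid-times.

    The running integral of Cp is computed under piecewise-linear
    interpolation of the parent-plasma curve.  Mid-times where Cp <= 0 are
    excluded with a warning.
    """
    t = tac.mid_times
    cp = np.asarray(inp.parent_plasma(t), dtype=float)
    cum = np.asarray(inp.parent_plasma_integral(t), dtype=float)
    pts = []
    for ti, cpi, cumi, ci in zip(t, cp, cum, tac.activity):
        if cpi <= 0:
            warnings.warn(
                f"Cp({ti:g} min) <= 0; Patlak point excluded", RuntimeWarning, stacklevel=2
            )
            continue
        pts.append((cumi / cpi, ci / cpi, float(ti)))
    return pts


def _fit_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """OLS slope, intercept, r².  Shared by TAC-level and voxelwise fits so
    the two routes are bitwise identical."""
    xm = x.mean()
    ym = y.mean()
    dx = x - xm
    sxx = float(np.dot(dx, dx))
    if sxx == 0.0:
        return np.nan, np.nan, np.nan
    slope = float(np.dot(dx, y - ym)) / sxx
    intercept = ym - slope * xm
    resid = y - (slope * x + intercept)
    ss_res = float(np.dot(resid, resid))
    ss_tot = float(np.dot(y - ym, y - ym))
    if ss_tot == 0.0:
        r2 = 1.0 if ss_res == 0.0 else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    return slope, intercept, r2


def patlak_fit(
    points: list[tuple[float, float, float]],
    t_star: float = 40.0,
    t_max: float | None = 70.0,
) -> PatlakFit:
    """Fit the Patlak line to points with mid-time in [t_star, t_max].

    Raises ``ValueError`` with fewer than two usable points.
    """
    sel = [
        (x, y)
        for x, y, tm in points
        if tm >= t_star and (t_max is None or tm <= t_max)
    ]
    if len(sel) < 2:
        raise ValueError(
            f"need >= 2 Patlak points with mid-time >= {t_star} min, got {len(sel)}"
        )
    x = np.array([p[0] for p in sel])
    y = np.array([p[1] for p in sel])
    slope, intercept, r2 = _fit_line(x, y)
    return PatlakFit(ki=slope, v=intercept, t_star=t_star, n_points=len(sel), r_squared=r2)


def patlak_image(
    img,
    inp: InputFunctionSet,
    t_star: float = 40.0,
    t_max: float | None = 70.0,
) -> ParametricImage:
    """Voxelwise Patlak fit over the [t_star, t_max] window.

    Identical arithmetic to looping :func:`patlak_fit` over voxel TACs
    (same code path per voxel); unfittable voxels (non-finite values,
    degenerate abscissa) get NaN.

    Parameters
    ----------
    img
        :class:`~fespet.phantom.DynamicImage` (4D activity + schedule).
    """
    sch = img.schedule
    mids = sch.mid_times
    cp = np.asarray(inp.parent_plasma(mids), dtype=float)
    cum = np.asarray(inp.parent_plasma_integral(mids), dtype=float)
    ok = cp > 0
    sel = ok & (mids >= t_star)
    if t_max is not None:
        sel &= mids <= t_max
    if int(sel.sum()) < 2:
        raise ValueError("Patlak window contains fewer than two usable frames")
    if not np.all(ok[(mids >= t_star) & ((mids <= t_max) if t_max is not None else True)]):
        warnings.warn("frames with Cp <= 0 excluded from Patlak window", RuntimeWarning)
    x = cum[sel] / cp[sel]
    cp_sel = cp[sel]

    spatial = img.data.shape[:3]
    flat = img.data.reshape(-1, img.data.shape[3])[:, sel]
    y_all = flat / cp_sel  # y = C(t)/Cp(t) per voxel
    nvox = y_all.shape[0]
    ki = np.full(nvox, np.nan)
    v = np.full(nvox, np.nan)
    r2 = np.full(nvox, np.nan)
    for i in range(nvox):
        y = y_all[i]
        if not np.all(np.isfinite(y)):
            continue
        s, b, r = _fit_line(x, y)
        ki[i], v[i], r2[i] = s, b, r
    return ParametricImage(
        ki=ki.reshape(spatial),
        v=v.reshape(spatial),
        r_squared=r2.reshape(spatial),
        voxel_size_mm=tuple(img.voxel_size_mm),
        t_star=t_star,
        t_max=t_max,
    )
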