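"""SUV images, lesion VOIs and detectability metrics (TBR, CNR) with the
paired log-ratio comparison of parametric Ki images against SUV images.

TBR = mean(target) / mean(background);
CNR = (mean(target) - mean(background)) / SD(background),
with the population SD over background voxels.  Image types are compared
per lesion by log-transformed paired t-tests; the exponentiated mean log
difference is reported as the ratio ("median ratio") with its 95% CI.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy import stats

from .image import DynamicImage

__all__ = [
    "SUVImage",
    "LesionRecord",
    "RatioComparison",
    "suv_image",
    "isocontour_voi",
    "lesion_stats",
    "compare_image_types",
    "screen_lesions",
    "background_shell",
    "SUVMAX_INCLUSION_THRESHOLD",
]

#: Lesions with SUVmax below this are excluded from visibility analysis.
SUVMAX_INCLUSION_THRESHOLD = 1.5


@dataclass
class SUVImage:
    """Static SUV volume [g/mL], body-weight normalised.

    SUV = concentration [kBq/mL] * body_weight [kg] / injected_dose [MBq];
    the kg->g and MBq->kBq factors (1000 each) cancel exactly.
    """

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    injected_dose_mbq: float
    body_weight_kg: float
    window_min: tuple[float, float] = (60.0, 70.0)


@dataclass
class LesionRecord:
    lesion_id: str
    voi_mask: np.ndarray
    background_mask: np.ndarray | None
    suv_max: float
    suv_mean: float
    included: bool


@dataclass(frozen=True)
class RatioComparison:
    """Paired log-ratio comparison of a metric between two image types."""

    n_pairs: int
    ratio: float  # geometric-mean ratio exp(mean log difference)
    ci_low: float
    ci_high: float
    p_value: float
    n_higher: int  # pairs where the Ki-image value is strictly higher


def suv_image(
    img: DynamicImage,
    injected_dose_mbq: float,
    body_weight_kg: float,
    window_min: tuple[float, float] = (60.0, 70.0),
) -> SUVImage:
    """Duration-weighted mean of the frames inside ``window_min``, scaled to SUV.

    The window must be tiled exactly by frame intervals; frames that
    straddle a window edge raise an error naming them.
    """
    if injected_dose_mbq <= 0 or body_weight_kg <= 0:
        raise ValueError("dose and weight must be positive")
    a, b = window_min
    sch = img.schedule
    inside = [i for i, (s, e) in enumerate(sch.frames) if s >= a and e <= b]
    straddle = [
        (s, e)
        for s, e in sch.frames
        if (s < a < e) or (s < b < e)
    ]
    if straddle:
        raise ValueError(
            f"SUV window {window_min} is not aligned to frame boundaries; "
            f"offending frames: {straddle}"
        )
    if not inside:
        raise ValueError(f"no frames inside SUV window {window_min}")
    covered = sum(sch.durations[i] for i in inside)
    if abs(covered - (b - a)) > 1e-9:
        raise ValueError(
            f"frames cover only {covered:g} of the {b - a:g} min SUV window"
        )
    dur = sch.durations[inside]
    mean_act = np.tensordot(img.data[..., inside], dur / dur.sum(), axes=([3], [0]))
    suv = mean_act * body_weight_kg / injected_dose_mbq
    return SUVImage(
        data=suv,
        voxel_size_mm=img.voxel_size_mm,
        injected_dose_mbq=injected_dose_mbq,
        body_weight_kg=body_weight_kg,
        window_min=(float(a), float(b)),
    )


_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def isocontour_voi(
    image3d: np.ndarray, seed_mask: np.ndarray, margin_voxels: int = 1
) -> np.ndarray:
    """50% isocontour VOI around the hottest voxel of ``seed_mask``.

    The maximum voxel within the seed mask is found (ties broken by lowest
    linear index); the VOI is the 26-connected component containing it
    among voxels >= 0.5 * max, restricted to the seed's bounding box padded
    by ``margin_voxels``.
    """
    img = np.asarray(image3d, dtype=float)
    seed = np.asarray(seed_mask, dtype=bool)
    if seed.shape != img.shape:
        raise ValueError("seed mask shape must match image")
    if not seed.any():
        raise ValueError("seed mask is empty")
    masked = np.where(seed, img, -np.inf)
    peak_flat = int(np.argmax(masked))  # argmax returns the lowest tied index
    peak = np.unravel_index(peak_flat, img.shape)
    vmax = img[peak]

    region = np.zeros_like(seed)
    sl = tuple(
        slice(max(int(i.min()) - margin_voxels, 0), min(int(i.max()) + margin_voxels + 1, n))
        for i, n in zip(np.nonzero(seed), img.shape)
    )
    region[sl] = True
    thresh = region & (img >= 0.5 * vmax)
    labels, _ = ndimage.label(thresh, structure=_STRUCT_26)
    return labels == labels[peak]


def lesion_stats(
    image3d: np.ndarray, voi_mask: np.ndarray, bg_mask: np.ndarray
) -> tuple[float, float]:
    """(TBR, CNR) of a target VOI against a background region.

    Background SD is the population SD.  Raises if either mask is empty,
    the background mean is zero (TBR undefined) or the background SD is
    zero (CNR undefined).
    """
    img = np.asarray(image3d, dtype=float)
    voi = np.asarray(voi_mask, dtype=bool)
    bg = np.asarray(bg_mask, dtype=bool)
    if not voi.any():
        raise ValueError("target VOI is empty")
    if not bg.any():
        raise ValueError("background mask is empty")
    tmean = img[voi].mean()
    bmean = img[bg].mean()
    bsd = img[bg].std()  # population SD
    if bmean == 0:
        raise ValueError("background mean is zero; TBR undefined")
    if bsd == 0:
        raise ValueError("background SD is zero; CNR undefined")
    return float(tmean / bmean), float((tmean - bmean) / bsd)


def compare_image_types(
    pairs: list[tuple[float, float]], confidence: float = 0.95
) -> RatioComparison:
    """Paired log-ratio analysis of per-lesion (value_suv, value_ki) pairs.

    d_i = log(ki_i) - log(suv_i); the reported ratio is exp(mean d) with a
    t-based CI on the log scale and a two-sided paired t-test p-value.
    """
    if len(pairs) < 2:
        raise ValueError("need at least 2 pairs")
    bad = [i for i, (s, k) in enumerate(pairs) if s <= 0 or k <= 0]
    if bad:
        raise ValueError(f"non-positive values for pair indices {bad}")
    suv = np.array([p[0] for p in pairs], dtype=float)
    ki = np.array([p[1] for p in pairs], dtype=float)
    d = np.log(ki) - np.log(suv)
    n = d.size
    mean_d = d.mean()
    sd_d = d.std(ddof=1)
    se = sd_d / np.sqrt(n)
    if se <= 1e-12 * max(abs(mean_d), 1.0):  # numerically constant ratios
        lo = hi = float(np.exp(mean_d))
        p = 1.0 if mean_d == 0 else 0.0
    else:
        tcrit = stats.t.ppf(0.5 + confidence / 2.0, n - 1)
        lo = float(np.exp(mean_d - tcrit * se))
        hi = float(np.exp(mean_d + tcrit * se))
        p = float(stats.ttest_rel(np.log(ki), np.log(suv)).pvalue)
    return RatioComparison(
        n_pairs=n,
        ratio=float(np.exp(mean_d)),
        ci_low=lo,
        ci_high=hi,
        p_value=p,
        n_higher=int(np.sum(ki > suv)),
    )


def screen_lesions(
    suv: SUVImage,
    candidates: dict[str, np.ndarray],
    backgrounds: dict[str, np.ndarray] | None = None,
    threshold: float = SUVMAX_INCLUSION_THRESHOLD,
) -> list[LesionRecord]:
    """Apply the SUVmax inclusion rule to candidate lesion VOIs.

    A lesion is included iff its SUVmax is >= ``threshold`` (1.5 by
    default, with equality included).
    """
    records = []
    for name, mask in candidates.items():
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise ValueError(f"candidate VOI {name!r} is empty")
        vals = suv.data[mask]
        smax = float(vals.max())
        records.append(
            LesionRecord(
                lesion_id=name,
                voi_mask=mask,
                background_mask=None if backgrounds is None else backgrounds.get(name),
                suv_max=smax,
                suv_mean=float(vals.mean()),
                included=smax >= threshold,
            )
        )
    return records


def background_shell(
    lesion_mask: np.ndarray,
    host_mask: np.ndarray | None = None,
    dilation_voxels: int = 3,
) -> np.ndarray:
    """Default background region: the lesion mask dilated by
    ``dilation_voxels`` minus the lesion itself, clipped to the host organ."""
    lesion = np.asarray(lesion_mask, dtype=bool)
    dil = ndimage.binary_dilation(lesion, structure=_STRUCT_26, iterations=dilation_voxels)
    shell = dil & ~lesion
    if host_mask is not None:
        shell &= np.asarray(host_mask, dtype=bool)
    return shell
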