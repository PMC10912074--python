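"""Synthetic blood data, tissue TACs and 4D phantom images.

The generator emulates the statistical structure a dynamic whole-body
[18F]FES study produces: a bolus-shaped whole-blood curve with metabolite
time course, organ time-activity curves driven by two-tissue compartment
kinetics (liver holding ~30% of the injected dose around 30 min),
spherical lesions with irreversible uptake on heterogeneous backgrounds,
optional isotropic PSF blurring (partial-volume/spill-in effects), and
Gaussian frame noise with variance proportional to activity over frame
duration — the standard TAC-level approximation of reconstructed PET
noise.  All activities are decay-corrected to injection time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .image import DynamicImage
from .input_function import InputFunctionSet, make_input_function
from .kinetics import KineticParams, ModelContext, model_tac
from .schedule import FrameSchedule, default_schedule
from .tac import TimeActivityCurve

__all__ = [
    "Sphere",
    "Ellipsoid",
    "Cylinder",
    "Region",
    "PhantomSpec",
    "BloodSampleTable",
    "simulate_tac",
    "build_phantom",
    "sample_blood",
    "default_phantom_spec",
    "BLOOD_SAMPLE_TIMES_MIN",
    "DEFAULT_TAC_NOISE",
]

#: Venous sampling times used during the scan [min].
BLOOD_SAMPLE_TIMES_MIN: tuple[float, ...] = (2.0, 5.0, 10.0, 20.0, 40.0, 60.0, 120.0)

#: Default noise coefficient for VOI-level TACs (SD = a*sqrt(C/dur)); gives
#: ~1-2% noise on a 10 kBq/mL tissue curve in 5-min frames, the level seen
#: for organ VOI means.
DEFAULT_TAC_NOISE = 0.1

#: Default voxel-level noise coefficient; ~10-15% per voxel-frame at tissue
#: activities, matching reconstructed whole-body-pass image noise.
DEFAULT_VOXEL_NOISE = 1.0


# --------------------------------------------------------------------------
# geometric primitives (coordinates and sizes in mm)


@dataclass(frozen=True)
class Sphere:
    center_mm: tuple[float, float, float]
    diameter_mm: float

    def __post_init__(self) -> None:
        if self.diameter_mm <= 0:
            raise ValueError("sphere diameter must be positive")

    def bounds(self):
        r = self.diameter_mm / 2.0
        c = self.center_mm
        return tuple(ci - r for ci in c), tuple(ci + r for ci in c)

    def contains(self, pts: np.ndarray) -> np.ndarray:
        r = self.diameter_mm / 2.0
        d2 = ((pts - np.asarray(self.center_mm)) ** 2).sum(axis=-1)
        return d2 <= r * r


@dataclass(frozen=True)
class Ellipsoid:
    center_mm: tuple[float, float, float]
    radii_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.radii_mm):
            raise ValueError("ellipsoid radii must be positive")

    def bounds(self):
        c, r = self.center_mm, self.radii_mm
        return tuple(ci - ri for ci, ri in zip(c, r)), tuple(
            ci + ri for ci, ri in zip(c, r)
        )

    def contains(self, pts: np.ndarray) -> np.ndarray:
        u = (pts - np.asarray(self.center_mm)) / np.asarray(self.radii_mm)
        return (u * u).sum(axis=-1) <= 1.0


@dataclass(frozen=True)
class Cylinder:
    """Axis-aligned circular cylinder (axis along z)."""

    center_xy_mm: tuple[float, float]
    radius_mm: float
    z_range_mm: tuple[float, float]

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("cylinder radius must be positive")
        if self.z_range_mm[1] <= self.z_range_mm[0]:
            raise ValueError("cylinder z_range must be increasing")

    def bounds(self):
        cx, cy = self.center_xy_mm
        r = self.radius_mm
        z0, z1 = self.z_range_mm
        return (cx - r, cy - r, z0), (cx + r, cy + r, z1)

    def contains(self, pts: np.ndarray) -> np.ndarray:
        cx, cy = self.center_xy_mm
        d2 = (pts[..., 0] - cx) ** 2 + (pts[..., 1] - cy) ** 2
        inz = (pts[..., 2] >= self.z_range_mm[0]) & (pts[..., 2] <= self.z_range_mm[1])
        return (d2 <= self.radius_mm**2) & inz


@dataclass(frozen=True)
class Region:
    """Named geometric region with its kinetics (or a literal TAC)."""

    name: str
    shape: Sphere | Ellipsoid | Cylinder
    kinetics: KineticParams | None = None
    tac: np.ndarray | None = None  # literal per-frame activity [kBq/mL]

    def __post_init__(self) -> None:
        if (self.kinetics is None) == (self.tac is None):
            raise ValueError(f"region {self.name!r}: give exactly one of kinetics or tac")


@dataclass
class PhantomSpec:
    """Full description of a synthetic 4D phantom.

    Regions are painted in order (organs first, lesions last); later regions
    overwrite earlier ones where they overlap, so lesion voxels are excluded
    from their host organ's mask.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 48)
    voxel_size_mm: tuple[float, float, float] = (4.0, 4.0, 4.0)
    organs: list[Region] = field(default_factory=list)
    lesions: list[Region] = field(default_factory=list)
    injected_dose_mbq: float = 200.0
    body_weight_kg: float = 70.0
    psf_fwhm_mm: float = 6.0
    noise_coefficient: float = DEFAULT_VOXEL_NOISE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.injected_dose_mbq <= 0:
            raise ValueError("injected_dose_mbq must be positive")
        if self.body_weight_kg <= 0:
            raise ValueError("body_weight_kg must be positive")
        size = tuple(n * v for n, v in zip(self.grid_shape, self.voxel_size_mm))
        for reg in list(self.organs) + list(self.lesions):
            lo, hi = reg.shape.bounds()
            if any(l < 0 for l in lo) or any(h > s for h, s in zip(hi, size)):
                raise ValueError(
                    f"region {reg.name!r} extends outside the grid "
                    f"(bounds {lo}..{hi}, grid size {size} mm)"
                )

    @property
    def voxel_volume_ml(self) -> float:
        vx, vy, vz = self.voxel_size_mm
        return vx * vy * vz / 1000.0


@dataclass
class BloodSampleTable:
    """Measured venous blood samples."""

    time_min: np.ndarray
    whole_blood: np.ndarray  # kBq/mL
    plasma: np.ndarray  # kBq/mL (total plasma activity incl. metabolites)
    parent_fraction: np.ndarray

    def __post_init__(self) -> None:
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.whole_blood = np.asarray(self.whole_blood, dtype=float)
        self.plasma = np.asarray(self.plasma, dtype=float)
        self.parent_fraction = np.asarray(self.parent_fraction, dtype=float)
        n = self.time_min.size
        if any(a.size != n for a in (self.whole_blood, self.plasma, self.parent_fraction)):
            raise ValueError("all columns must have equal length")
        if np.any(self.time_min <= 0) or np.any(np.diff(self.time_min) <= 0):
            raise ValueError("sample times must be positive and increasing")
        if np.any((self.parent_fraction < 0) | (self.parent_fraction > 1)):
            raise ValueError("parent fractions must be in [0, 1]")

    def __len__(self) -> int:
        return int(self.time_min.size)


# --------------------------------------------------------------------------
# operations


def _frame_noise_sd(mean: np.ndarray, durations: np.ndarray, alpha: float) -> np.ndarray:
    return alpha * np.sqrt(np.maximum(mean, 0.0) / durations)


def simulate_tac(
    kp: KineticParams,
    inp: InputFunctionSet,
    schedule: FrameSchedule,
    noise_coefficient: float = 0.0,
    seed: int = 0,
    context: ModelContext | None = None,
) -> TimeActivityCurve:
    """Frame-averaged 2TCM tissue curve with optional Gaussian frame noise.

    Noise is zero-mean Gaussian with SD = a*sqrt(mean_frame_activity /
    frame_duration); ``noise_coefficient = 0`` returns the noiseless curve.
    The same seed always reproduces the same realisation.
    """
    tac = model_tac(kp, inp, schedule, context=context)
    if noise_coefficient == 0.0:
        return tac
    rng = np.random.default_rng(seed)
    sd = _frame_noise_sd(tac.activity, schedule.durations, noise_coefficient)
    noisy = tac.activity + rng.normal(0.0, 1.0, tac.activity.shape) * sd
    return TimeActivityCurve(
        mid_times=tac.mid_times, durations=tac.durations, activity=noisy, label=tac.label
    )


def _voxel_centers(spec: PhantomSpec) -> np.ndarray:
    axes = [
        (np.arange(n) + 0.5) * v for n, v in zip(spec.grid_shape, spec.voxel_size_mm)
    ]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    return np.stack([gx, gy, gz], axis=-1)


def build_phantom(
    spec: PhantomSpec,
    inp: InputFunctionSet | None = None,
    schedule: FrameSchedule | None = None,
    context: ModelContext | None = None,
) -> tuple[DynamicImage, dict[str, np.ndarray]]:
    """Rasterise the phantom spec into a 4D dynamic image plus region masks.

    Each voxel receives the noiseless frame-averaged TAC of the region that
    owns it (lesions painted last); an optional isotropic Gaussian PSF is
    applied per frame, then voxelwise Gaussian noise as in
    :func:`simulate_tac`.  Region masks reflect ownership after overlaps.
    """
    inp = inp if inp is not None else make_input_function()
    schedule = schedule if schedule is not None else default_schedule()
    ctx = context if context is not None else ModelContext(inp, schedule)

    regions = list(spec.organs) + list(spec.lesions)
    if not regions:
        raise ValueError("phantom spec contains no regions")
    centers = _voxel_centers(spec)
    labels = np.full(spec.grid_shape, -1, dtype=np.int32)
    for idx, reg in enumerate(regions):
        labels[reg.shape.contains(centers)] = idx

    n_frames = len(schedule)
    tacs = np.zeros((len(regions) + 1, n_frames))
    for idx, reg in enumerate(regions):
        if reg.kinetics is not None:
            tacs[idx] = model_tac(reg.kinetics, inp, schedule, context=ctx).activity
        else:
            if len(reg.tac) != n_frames:
                raise ValueError(f"region {reg.name!r}: literal TAC length mismatch")
            tacs[idx] = np.asarray(reg.tac, dtype=float)
    # label -1 (air) maps to the trailing all-zero row
    data = tacs[labels]  # (x, y, z, frame)

    if spec.psf_fwhm_mm > 0:
        sigma_vox = [
            spec.psf_fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / v
            for v in spec.voxel_size_mm
        ]
        for f in range(n_frames):
            data[..., f] = gaussian_filter(data[..., f], sigma=sigma_vox, mode="constant")

    if spec.noise_coefficient > 0:
        rng = np.random.default_rng(spec.seed)
        sd = _frame_noise_sd(data, schedule.durations, spec.noise_coefficient)
        data = data + rng.standard_normal(data.shape) * sd

    masks = {reg.name: labels == idx for idx, reg in enumerate(regions)}
    img = DynamicImage(data=data, voxel_size_mm=spec.voxel_size_mm, schedule=schedule)
    return img, masks


def sample_blood(
    inp: InputFunctionSet,
    times: tuple[float, ...] = BLOOD_SAMPLE_TIMES_MIN,
    noise_cv: float = 0.03,
    seed: int = 0,
    pf_noise_sd: float = 0.02,
) -> BloodSampleTable:
    """Simulate measured venous blood samples.

    Whole-blood and total-plasma activities get independent multiplicative
    Gaussian noise (coefficient of variation ``noise_cv``); measured parent
    fractions get additive Gaussian noise (SD ``pf_noise_sd`` when
    ``noise_cv > 0``) clipped to [0, 1].
    """
    t = np.asarray(times, dtype=float)
    if np.any(t <= 0):
        raise ValueError("sample times must be positive")
    rng = np.random.default_rng(seed)
    wb_true = np.asarray(inp.whole_blood(t), dtype=float)
    plasma_true = wb_true * inp.p2wb_ratio
    pf_true = np.asarray(inp.parent_fraction(t), dtype=float)
    if noise_cv > 0:
        wb = wb_true * (1.0 + noise_cv * rng.standard_normal(t.size))
        plasma = plasma_true * (1.0 + noise_cv * rng.standard_normal(t.size))
        pf = np.clip(pf_true + pf_noise_sd * rng.standard_normal(t.size), 0.0, 1.0)
    else:
        wb, plasma, pf = wb_true, plasma_true, pf_true
    return BloodSampleTable(time_min=t, whole_blood=wb, plasma=plasma, parent_fraction=pf)


# --------------------------------------------------------------------------
# default phantom


#: Default lesion set: spheres 8-25 mm with irreversible kinetics spanning
#: the uptake range seen in ER+ metastases (SUVmean a few g/mL).
_DEFAULT_LESIONS: tuple[tuple[str, tuple[float, float, float], float, KineticParams], ...] = (
    ("lesion_01", (90.0, 80.0, 140.0), 8.0, KineticParams(0.13, 0.20, 0.06, 0.0, 0.08)),
    ("lesion_02", (200.0, 70.0, 120.0), 10.0, KineticParams(0.13, 0.18, 0.08, 0.0, 0.10)),
    ("lesion_03", (70.0, 180.0, 100.0), 12.0, KineticParams(0.15, 0.15, 0.08, 0.0, 0.08)),
    ("lesion_04", (128.0, 190.0, 110.0), 14.0, KineticParams(0.15, 0.15, 0.10, 0.0, 0.10)),
    ("lesion_05", (100.0, 60.0, 150.0), 16.0, KineticParams(0.15, 0.12, 0.10, 0.0, 0.12)),
    ("lesion_06", (180.0, 180.0, 150.0), 18.0, KineticParams(0.16, 0.12, 0.12, 0.0, 0.10)),
    ("lesion_07", (60.0, 100.0, 150.0), 20.0, KineticParams(0.18, 0.10, 0.12, 0.0, 0.12)),
    ("lesion_08", (200.0, 160.0, 150.0), 25.0, KineticParams(0.20, 0.10, 0.15, 0.0, 0.10)),
)

#: Liver kinetic shape (K1 is re-scaled by the %ID calibration below).
_LIVER_SHAPE = KineticParams(K1=0.8, k2=0.15, k3=0.03, k4=0.0, vB=0.20)
#: Background soft tissue: fast equilibration (within minutes, as muscle
#: and breast tissue level off early) with mild irreversible trapping.
_SOFT_TISSUE = KineticParams(K1=0.40, k2=0.25, k3=0.004, k4=0.0, vB=0.04)
_BONE = KineticParams(K1=0.13, k2=0.25, k3=0.03, k4=0.0, vB=0.05)

#: Target fraction of injected dose in the liver around 30 min.
LIVER_ID_FRACTION = 0.30
LIVER_ID_TIME_MIN = 30.0


def default_phantom_spec(
    inp: InputFunctionSet | None = None,
    schedule: FrameSchedule | None = None,
    noise_coefficient: float = DEFAULT_VOXEL_NOISE,
    psf_fwhm_mm: float = 6.0,
    seed: int = 0,
) -> PhantomSpec:
    """The default 64x64x48 (4 mm voxel) whole-body phantom.

    Organs: soft-tissue body, two bone regions, a ~1.4 L liver ellipsoid
    and a descending-aorta cylinder (pure blood, the IDIF source).  Eight
    spherical lesions (8-25 mm) with irreversible uptake are placed in soft
    tissue and bone.  Liver K1 is calibrated so that the liver mask holds
    ``LIVER_ID_FRACTION`` of the injected dose in the frame covering 30 min.
    """
    inp = inp if inp is not None else make_input_function()
    schedule = schedule if schedule is not None else default_schedule()

    organs = [
        Region("body", Ellipsoid((128.0, 128.0, 96.0), (120.0, 120.0, 92.0)), _SOFT_TISSUE),
        Region("spine", Cylinder((128.0, 190.0), 12.0, (12.0, 180.0)), _BONE),
        Region("pelvic_bone", Sphere((70.0, 60.0, 170.0), 36.0), _BONE),
        Region("liver", Ellipsoid((162.0, 115.0, 52.0), (90.0, 78.0, 45.0)), _LIVER_SHAPE),
        Region("aorta", Cylinder((50.0, 128.0), 9.0, (20.0, 170.0)), KineticParams(0.0, 0.0, 0.0, 0.0, 1.0)),
    ]
    lesions = [
        Region(name, Sphere(center, diam), kp)
        for name, center, diam, kp in _DEFAULT_LESIONS
    ]
    spec = PhantomSpec(
        organs=organs,
        lesions=lesions,
        noise_coefficient=noise_coefficient,
        psf_fwhm_mm=psf_fwhm_mm,
        seed=seed,
    )
    spec.organs[3] = replace(
        spec.organs[3], kinetics=_calibrated_liver(spec, inp, schedule)
    )
    return spec


def _calibrated_liver(
    spec: PhantomSpec, inp: InputFunctionSet, schedule: FrameSchedule
) -> KineticParams:
    """Scale liver K1 so the voxelised liver mask holds LIVER_ID_FRACTION of
    the injected dose in the frame covering LIVER_ID_TIME_MIN."""
    centers = _voxel_centers(spec)
    regions = list(spec.organs) + list(spec.lesions)
    liver_idx = next(i for i, r in enumerate(regions) if r.name == "liver")
    owner = np.full(spec.grid_shape, -1, dtype=np.int32)
    for idx, reg in enumerate(regions):
        owner[reg.shape.contains(centers)] = idx
    n_liver = int((owner == liver_idx).sum())
    if n_liver == 0:
        raise ValueError("liver mask is empty on this grid")
    v_liver_ml = n_liver * spec.voxel_volume_ml

    frame = schedule.frame_at(LIVER_ID_TIME_MIN)
    ctx = ModelContext(inp, schedule)
    shape = _LIVER_SHAPE
    unit = replace(shape, K1=1.0, vB=0.0)
    c_unit = model_tac(unit, inp, schedule, context=ctx).activity[frame]
    c_blood = shape.vB * ctx.cwb_frames[frame]
    target = LIVER_ID_FRACTION * spec.injected_dose_mbq * 1000.0 / v_liver_ml  # kBq/mL
    k1 = (target - c_blood) / c_unit
    if k1 <= 0:
        raise ValueError("liver calibration failed: blood signal exceeds target")
    return replace(shape, K1=float(k1))
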