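"""In-memory image containers."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .schedule import FrameSchedule

__all__ = ["DynamicImage"]


@dataclass
class DynamicImage:
    """4D dynamic PET volume: (x, y, z, frame) activity in kBq/mL.

    Activities are decay-corrected to injection time, as produced by
    clinical reconstruction.
    """

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    schedule: FrameSchedule

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError("dynamic image data must be 4D (x, y, z, frame)")
        if self.data.shape[3] != len(self.schedule):
            raise ValueError(
                f"frame axis ({self.data.shape[3]}) does not match schedule "
                f"({len(self.schedule)} frames)"
            )
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)

    @property
    def voxel_volume_ml(self) -> float:
        """Voxel volume in mL (1 mL = 1000 mm³)."""
        vx, vy, vz = self.voxel_size_mm
        return vx * vy * vz / 1000.0
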