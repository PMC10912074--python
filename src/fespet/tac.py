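"""Time-activity curve container."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TimeActivityCurve"]


@dataclass
class TimeActivityCurve:
    """Frame-sampled activity concentration in a region.

    Attributes
    ----------
    mid_times
        Frame mid-times [min], strictly increasing.
    durations
        Frame durations [min], all positive.
    activity
        Mean activity concentration per frame [kBq/mL].
    label
        Optional region name.
    """

    mid_times: np.ndarray
    durations: np.ndarray
    activity: np.ndarray
    label: str | None = field(default=None)

    def __post_init__(self) -> None:
        self.mid_times = np.asarray(self.mid_times, dtype=float)
        self.durations = np.asarray(self.durations, dtype=float)
        self.activity = np.asarray(self.activity, dtype=float)
        n = self.mid_times.size
        if self.durations.size != n or self.activity.size != n:
            raise ValueError("mid_times, durations and activity must have equal length")
        if n == 0:
            raise ValueError("empty TAC")
        if np.any(np.diff(self.mid_times) <= 0):
            raise ValueError("mid_times must be strictly increasing")
        if np.any(self.durations <= 0):
            raise ValueError("durations must be positive")

    def __len__(self) -> int:
        return int(self.mid_times.size)
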