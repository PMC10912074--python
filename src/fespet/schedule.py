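"""Acquisition frame schedules for dynamic whole-body PET.

A dynamic whole-body (D-WB) protocol acquires an early dynamic series over
the chest followed by repeated whole-body passes, with a mid-scan pause for
patient comfort.  Frames are modelled as whole-volume intervals; the
continuous-bed-motion geometry of the scanner is not represented.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["FrameSchedule", "default_schedule"]


@dataclass(frozen=True)
class FrameSchedule:
    """Ordered acquisition frames, in minutes post-injection.

    Parameters
    ----------
    frames
        Sequence of ``(start_min, end_min)`` pairs, strictly increasing and
        non-overlapping.  A gap between consecutive frames (e.g. a mid-scan
        intermission) is allowed.
    pass_labels
        Optional tag per frame, e.g. ``early-dynamic``, ``WB-pass-3``,
        ``post-pause-pass-1``.
    """

    frames: tuple[tuple[float, float], ...]
    pass_labels: tuple[str, ...] | None = field(default=None)

    def __post_init__(self) -> None:
        frames = tuple((float(a), float(b)) for a, b in self.frames)
        object.__setattr__(self, "frames", frames)
        if len(frames) == 0:
            raise ValueError("schedule must contain at least one frame")
        prev_end = 0.0
        for i, (a, b) in enumerate(frames):
            if a < 0 or b < 0:
                raise ValueError(f"frame {i}: negative time ({a}, {b})")
            if b <= a:
                raise ValueError(f"frame {i}: end {b} must exceed start {a}")
            if i > 0 and a < prev_end:
                raise ValueError(f"frame {i} overlaps previous frame")
            prev_end = b
        if self.pass_labels is not None:
            labels = tuple(str(s) for s in self.pass_labels)
            if len(labels) != len(frames):
                raise ValueError("pass_labels length must match frames")
            object.__setattr__(self, "pass_labels", labels)

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def starts(self) -> np.ndarray:
        return np.array([a for a, _ in self.frames])

    @property
    def ends(self) -> np.ndarray:
        return np.array([b for _, b in self.frames])

    @property
    def mid_times(self) -> np.ndarray:
        """Frame mid-times, (start + end) / 2."""
        return (self.starts + self.ends) / 2.0

    @property
    def durations(self) -> np.ndarray:
        return self.ends - self.starts

    @property
    def total_scanned_min(self) -> float:
        """Summed frame duration (excludes gaps)."""
        return float(self.durations.sum())

    def frame_at(self, t: float) -> int:
        """Index of the frame whose interval ``[start, end)`` contains *t*.

        Raises ``ValueError`` if *t* falls in a gap or outside the schedule.
        """
        for i, (a, b) in enumerate(self.frames):
            if a <= t < b:
                return i
        if t == self.frames[-1][1]:
            return len(self.frames) - 1
        raise ValueError(f"t={t} min not covered by any frame")

    def frames_in_window(self, start: float, end: float) -> list[int]:
        """Indices of frames fully inside ``[start, end]``."""
        return [
            i for i, (a, b) in enumerate(self.frames) if a >= start and b <= end
        ]


def default_schedule() -> FrameSchedule:
    """The default D-WB [18F]FES acquisition schedule.

    Two sessions separated by a 10 min intermission:

    * 0–6 min: early dynamic over the chest, framed 12 x 10 s then 4 x 60 s
      (fine early framing resolves the bolus peak);
    * 6–20 min: 7 x 2 min whole-body passes;
    * 20–70 min: 10 x 5 min whole-body passes (the last six cover the
      40–70 min Patlak window; the last two cover the 60–70 min SUV window);
    * 70–80 min: intermission (no frames);
    * 80–120 min: 8 x 5 min post-pause passes.
    """
    frames: list[tuple[float, float]] = []
    labels: list[str] = []
    t = 0.0
    for _ in range(12):
        frames.append((t, t + 10.0 / 60.0))
        labels.append("early-dynamic")
        t += 10.0 / 60.0
    for _ in range(4):
        frames.append((t, t + 1.0))
        labels.append("early-dynamic")
        t += 1.0
    for k in range(7):
        frames.append((t, t + 2.0))
        labels.append(f"WB-pass-{k + 1}")
        t += 2.0
    for k in range(10):
        frames.append((t, t + 5.0))
        labels.append(f"WB-pass-{k + 8}")
        t += 5.0
    t = 80.0  # 10 min intermission
    for k in range(8):
        frames.append((t, t + 5.0))
        labels.append(f"post-pause-pass-{k + 1}")
        t += 5.0
    return FrameSchedule(tuple(frames), tuple(labels))
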