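"""Core containers for dynamic PET data.

A dynamic PET acquisition is a 4D activity volume (x, y, z, frame) together
with a frame schedule giving the start and duration of every frame in
seconds.  Regional and voxel measurements are time-activity curves (TACs):
one activity value per frame, interpreted as the frame-duration-weighted
average of the underlying continuous tracer concentration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FrameSchedule",
    "TAC",
    "DynamicPETImage",
    "make_frame_schedule",
]


@dataclass(frozen=True)
class FrameSchedule:
    """Contiguous, non-overlapping frame timing in seconds post-injection.

    Parameters
    ----------
    start : array of float
        Frame start times in seconds, strictly increasing.
    duration : array of float
        Frame durations in seconds, all positive.  Frame ``k`` covers
        ``[start[k], start[k] + duration[k])`` and frames must tile the scan
        with no gaps or overlaps.
    """

    start: np.ndarray
    duration: np.ndarray

    def __post_init__(self) -> None:
        start = np.asarray(self.start, dtype=float)
        duration = np.asarray(self.duration, dtype=float)
        object.__setattr__(self, "start", start)
        object.__setattr__(self, "duration", duration)
        if start.ndim != 1 or duration.shape != start.shape:
            raise ValueError("start and duration must be 1-D arrays of equal length")
        if start.size == 0:
            raise ValueError("schedule must contain at least one frame")
        if np.any(duration <= 0):
            raise ValueError("all frame durations must be positive")
        if np.any(np.diff(start) <= 0):
            raise ValueError("frame starts must be strictly increasing")
        # contiguity: each frame starts where the previous one ends
        if not np.allclose(start[1:], start[:-1] + duration[:-1], atol=1e-6):
            raise ValueError("frames must be contiguous (no gaps or overlaps)")

    @classmethod
    def from_durations(cls, durations) -> "FrameSchedule":
        """Build a contiguous schedule starting at t = 0 from durations (s)."""
        durations = np.asarray(durations, dtype=float)
        starts = np.concatenate([[0.0], np.cumsum(durations)[:-1]])
        return cls(starts, durations)

    @property
    def n_frames(self) -> int:
        return int(self.start.size)

    @property
    def end(self) -> np.ndarray:
        """Frame end times in seconds."""
        return self.start + self.duration

    @property
    def mid(self) -> np.ndarray:
        """Frame midpoint times in seconds."""
        return self.start + 0.5 * self.duration

    @property
    def mid_minutes(self) -> np.ndarray:
        """Frame midpoint times in minutes (the kinetic-modelling time axis)."""
        return self.mid / 60.0

    @property
    def total_duration(self) -> float:
        """Total scan span in seconds."""
        return float(self.end[-1] - self.start[0])

    def __len__(self) -> int:
        return self.n_frames


#: Frame durations (s) of the 60-min, 22-frame dynamic protocol:
#: 4 x 30 s + 4 x 60 s + 4 x 120 s + 4 x 240 s + 6 x 300 s.
PROTOCOL_22_FRAME_DURATIONS = (
    [30.0] * 4 + [60.0] * 4 + [120.0] * 4 + [240.0] * 4 + [300.0] * 6
)


def make_frame_schedule() -> FrameSchedule:
    """Return the 22-frame, 60-min dynamic acquisition schedule.

    The protocol starts at injection and tiles the hour as
    4 x 30 s, 4 x 60 s, 4 x 120 s, 4 x 240 s, 6 x 300 s.
    """
    return FrameSchedule.from_durations(PROTOCOL_22_FRAME_DURATIONS)


@dataclass
class TAC:
    """A time-activity curve: one activity value (kBq/mL) per frame."""

    values: np.ndarray
    schedule: FrameSchedule

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size != self.schedule.n_frames:
            raise ValueError("TAC length must equal the number of frames")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("TAC values must be finite")

    def __len__(self) -> int:
        return self.values.size


@dataclass
class DynamicPETImage:
    """4D dynamic PET volume with frame timing.

    ``data`` has shape ``(nx, ny, nz, n_frames)`` in activity units
    (kBq/mL, already decay- and attenuation-corrected); ``voxel_size`` is the
    voxel edge length per axis in mm.
    """

    data: np.ndarray
    schedule: FrameSchedule
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("dynamic image must be 4D (x, y, z, frame)")
        if self.data.shape[-1] != self.schedule.n_frames:
            raise ValueError(
                f"frame axis ({self.data.shape[-1]}) does not match "
                f"schedule length ({self.schedule.n_frames})"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("dynamic image must be finite")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def voxel_tac(self, i: int, j: int, k: int) -> TAC:
        return TAC(self.data[i, j, k, :], self.schedule)

    def mean_tac(self, mask: np.ndarray) -> TAC:
        """Mean TAC over a boolean mask."""
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != self.grid_shape:
            raise ValueError("mask shape does not match image grid")
        if not mask.any():
            raise ValueError("mask is empty")
        return TAC(self.data[mask].mean(axis=0), self.schedule)
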