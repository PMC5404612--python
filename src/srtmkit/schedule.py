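"""Frame schedules: the temporal sampling grid shared by all dynamic TACs.

Dynamic PET data are reconstructed into contiguous time frames of varying
duration — short frames around the bolus peak, long frames in the washout
tail.  A :class:`FrameSchedule` records the start and end of every frame in
minutes; all time-activity curves in this package are frame averages on such
a schedule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["FrameSchedule", "make_frame_schedule", "DEFAULT_BINNING"]

#: The raclopride acquisition binning used throughout: 6 x 0.5, 3 x 1,
#: 2 x 2 and 22 x 5 min frames, 33 frames covering 120 min.
DEFAULT_BINNING: list[tuple[int, float]] = [(6, 0.5), (3, 1.0), (2, 2.0), (22, 5.0)]


@dataclass(frozen=True)
class FrameSchedule:
    """Contiguous frame timing grid, in minutes.

    Invariants: starts strictly increasing from 0, each frame has positive
    duration, and frames tile the scan without gaps
    (``frame_start[i+1] == frame_end[i]``).
    """

    frame_start: np.ndarray
    frame_end: np.ndarray

    def __post_init__(self) -> None:
        start = np.asarray(self.frame_start, dtype=float)
        end = np.asarray(self.frame_end, dtype=float)
        object.__setattr__(self, "frame_start", start)
        object.__setattr__(self, "frame_end", end)
        if start.ndim != 1 or start.shape != end.shape or start.size == 0:
            raise ValueError("frame_start and frame_end must be equal-length 1-D arrays")
        if start[0] != 0.0:
            raise ValueError("first frame must start at t=0")
        if not np.all(end > start):
            raise ValueError("every frame must have positive duration")
        if not np.allclose(start[1:], end[:-1], rtol=0.0, atol=1e-9):
            raise ValueError("frames must be contiguous (start[i+1] == end[i])")

    @property
    def n_frames(self) -> int:
        return int(self.frame_start.size)

    @property
    def duration(self) -> np.ndarray:
        """Frame durations, minutes."""
        return self.frame_end - self.frame_start

    @property
    def midpoint(self) -> np.ndarray:
        """Frame midpoints, minutes."""
        return 0.5 * (self.frame_start + self.frame_end)

    @property
    def total_minutes(self) -> float:
        return float(self.frame_end[-1])

    @classmethod
    def default(cls) -> "FrameSchedule":
        return make_frame_schedule(DEFAULT_BINNING)


def make_frame_schedule(spec: list[tuple[int, float]]) -> FrameSchedule:
    """Build a contiguous schedule from a ``(count, duration_minutes)`` list.

    Parameters
    ----------
    spec
        Blocks of identical frames, e.g. ``[(6, 0.5), (3, 1), (2, 2), (22, 5)]``
        for the 33-frame / 120-min raclopride protocol.
    """
    if not spec:
        raise ValueError("frame schedule spec must not be empty")
    durations: list[float] = []
    for count, dur in spec:
        if int(count) < 1:
            raise ValueError(f"frame count must be >= 1, got {count}")
        if not dur > 0:
            raise ValueError(f"frame duration must be > 0, got {dur}")
        durations.extend([float(dur)] * int(count))
    end = np.cumsum(durations)
    start = np.concatenate([[0.0], end[:-1]])
    return FrameSchedule(frame_start=start, frame_end=end)
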