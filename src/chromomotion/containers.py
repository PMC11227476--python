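"""Core in-memory containers shared across the pipeline.

Conventions
-----------
* Image arrays are indexed ``(t, z, y, x)`` (0-based); multi-channel stacks
  are ``(c, t, z, y, x)``.
* Physical coordinates are in micrometres, ordered ``(x, y, z)``; 2D
  trajectories simply omit ``z``.
* Time is in seconds; ``dt_s`` is the frame interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TimelapseStack", "Trajectory"]


@dataclass
class TimelapseStack:
    """Multi-channel 3D+time intensity stack with physical calibration.

    Parameters
    ----------
    data
        Array of shape ``(C, T, Z, Y, X)``.
    voxel_size_um
        Voxel extent ``(z, y, x)`` in µm.
    dt_s
        Frame interval in seconds.
    """

    data: np.ndarray
    voxel_size_um: tuple[float, float, float]
    dt_s: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 5:
            raise ValueError(
                f"expected (C, T, Z, Y, X) data, got ndim={self.data.ndim}"
            )
        if any(v <= 0 for v in self.voxel_size_um):
            raise ValueError("voxel sizes must be positive")
        if self.dt_s <= 0:
            raise ValueError("frame interval must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]

    @property
    def shape_tzyx(self) -> tuple[int, int, int, int]:
        return self.data.shape[1:]

    def channel(self, c: int) -> np.ndarray:
        """Return one channel as a ``(T, Z, Y, X)`` view."""
        return self.data[c]

    def frame(self, c: int, t: int) -> np.ndarray:
        """Return one ``(Z, Y, X)`` volume."""
        return self.data[c, t]


@dataclass
class Trajectory:
    """An ordered sequence of localisations of one tracked object.

    ``positions_um`` has shape ``(n_points, dims)`` with columns
    ``(x, y[, z])`` in µm; ``frames`` are the (strictly increasing)
    frame indices, so gaps are representable.
    """

    track_id: int
    frames: np.ndarray
    positions_um: np.ndarray
    dt_s: float
    resolution_tag: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.positions_um = np.atleast_2d(np.asarray(self.positions_um, dtype=float))
        if self.frames.ndim != 1 or len(self.frames) != len(self.positions_um):
            raise ValueError("frames and positions must align")
        if len(self.frames) > 1 and np.any(np.diff(self.frames) <= 0):
            raise ValueError("frames must be strictly increasing")

    @property
    def dims(self) -> int:
        return self.positions_um.shape[1]

    @property
    def n_points(self) -> int:
        return len(self.frames)

    @property
    def n_steps(self) -> int:
        """Number of inter-frame steps spanned, ``frames[-1] - frames[0]``."""
        if self.n_points < 2:
            return 0
        return int(self.frames[-1] - self.frames[0])

    @property
    def duration_s(self) -> float:
        return self.n_steps * self.dt_s

    @property
    def times_s(self) -> np.ndarray:
        return self.frames * self.dt_s
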