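"""Core containers shared by the quantitation modules.

Coordinate conventions
----------------------
Images are indexed ``[row, col]`` with row 0 at the top of the frame.  The
embryo is rendered/imaged in lateral view with dorsal up, so *dorsal* is
row 0 and *ventral* is increasing row index.  All physical distances are
reported in micrometres via the stack's ``pixel_size``; times are minutes
after first cleavage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.draw import polygon as _draw_polygon

ROLE_LEADING = "leading-cell"
ROLE_POCKET = "pocket-cell"
ROLE_OTHER = "other"


@dataclass
class TimeLapseStack:
    """A single-channel time-lapse movie with its acquisition metadata.

    Parameters
    ----------
    frames
        ``(T, H, W)`` intensity array in fluorescent units (8-bit grey-level
        semantics; values in [0, 255]).
    frame_interval
        Minutes between consecutive frames.
    t_start
        Time of frame 0, in minutes after first cleavage.
    pixel_size
        Micrometres per pixel.
    """

    frames: np.ndarray
    frame_interval: float = 2.0
    t_start: float = 240.0
    pixel_size: float = 0.15

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a (T, H, W) array with T >= 1")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple:
        return self.frames.shape

    def time_of(self, frame_index: int) -> float:
        """Minutes after first cleavage for a frame index."""
        return self.t_start + frame_index * self.frame_interval

    def frame_at_or_after(self, t: float) -> int:
        """First frame index whose acquisition time is >= ``t`` (clipped to 0)."""
        return max(0, int(np.ceil((t - self.t_start) / self.frame_interval - 1e-9)))


@dataclass
class CellROI:
    """A cell's spatial footprint plus its ventral-dorsal axis.

    ``polygon`` is an ``(N, 2)`` array of (row, col) vertices of a simple
    polygon.  ``axis`` is a ``(2, 2)`` array of the directed ventral->dorsal
    segment endpoints; ``leading_edge`` the ventral boundary segment.
    """

    cell_id: str
    role: str
    polygon: np.ndarray
    axis: np.ndarray
    leading_edge: np.ndarray

    def __post_init__(self) -> None:
        self.polygon = np.asarray(self.polygon, dtype=float)
        self.axis = np.asarray(self.axis, dtype=float)
        self.leading_edge = np.asarray(self.leading_edge, dtype=float)
        if self.polygon.ndim != 2 or self.polygon.shape[1] != 2 or len(self.polygon) < 3:
            raise ValueError(f"cell {self.cell_id}: polygon must be (N>=3, 2)")
        if self.axis.shape != (2, 2):
            raise ValueError(f"cell {self.cell_id}: axis must be two (row, col) endpoints")
        if self.leading_edge.shape != (2, 2):
            raise ValueError(f"cell {self.cell_id}: leading_edge must be two endpoints")
        # ventral end must lie ventral (larger row) of the dorsal end
        if self.axis[0, 0] < self.axis[1, 0]:
            raise ValueError(
                f"cell {self.cell_id}: axis must run ventral (larger row) -> dorsal"
            )

    def footprint_mask(self, shape: tuple) -> np.ndarray:
        """Boolean mask of the footprint polygon on a (H, W) grid."""
        rr, cc = _draw_polygon(self.polygon[:, 0], self.polygon[:, 1], shape)
        mask = np.zeros(shape, dtype=bool)
        mask[rr, cc] = True
        return mask

    @property
    def column_span(self) -> tuple:
        """(first, last+1) column range covered by the footprint."""
        lo = int(np.floor(self.polygon[:, 1].min()))
        hi = int(np.ceil(self.polygon[:, 1].max()))
        return lo, hi


@dataclass
class LineProfile:
    """Intensity samples along a ventral->dorsal line at 1 px spacing.

    Position 0 is the ventral end; ``cell_length`` is the physical length of
    the sampled segment in micrometres.
    """

    intensities: np.ndarray
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 1 or len(self.intensities) < 2:
            raise ValueError("profile needs at least 2 samples")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    def __len__(self) -> int:
        return len(self.intensities)

    @property
    def positions_um(self) -> np.ndarray:
        return np.arange(len(self.intensities)) * self.pixel_size

    @property
    def cell_length(self) -> float:
        return (len(self.intensities) - 1) * self.pixel_size


@dataclass
class Peak:
    """One supra-threshold region of a line profile."""

    start: int              # first index of the contiguous run
    stop: int               # one past the last index
    apex_index: int         # index of the run maximum (leftmost on ties)
    apex_height: float      # fluorescent units
    apex_position_um: float  # distance from the ventral end
    half: str | None = None  # 'ventral' | 'dorsal', set by assign_halves

    def __post_init__(self) -> None:
        if not (self.start <= self.apex_index < self.stop):
            raise ValueError("apex must lie inside the peak span")


@dataclass
class VDRatioResult:
    """Ventral:dorsal peak-count ratio pooled over a window of frames."""

    n_frames: int
    ventral_count: int
    dorsal_count: int

    @property
    def defined(self) -> bool:
        return self.dorsal_count > 0

    @property
    def ratio(self) -> float | None:
        if not self.defined:
            return None
        return self.ventral_count / self.dorsal_count
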