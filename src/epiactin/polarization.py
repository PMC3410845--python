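"""Leading-edge F-actin intensity and ventral:dorsal polarization scoring.

Implements the movie quantitation used for epidermal F-actin: a linear
contrast stretch for camera background, the 36x36 px leading-edge box mean,
ventral->dorsal line profiles, threshold peak detection (regions at least
10 fluorescent units above background), peak half-assignment, the 20-frame
ventral:dorsal peak-count ratio, and the apex-behind-front enrichment
offset.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage as ndi

from .core import CellROI, LineProfile, Peak, TimeLapseStack, VDRatioResult

PEAK_THRESHOLD = 10.0   # fluorescent units above background
BOX_PX = 36             # leading-edge box side length, px
WINDOW_FRAMES = 20      # frames pooled for the V:D ratio (40 min at 2 min/frame)
FRONT_MARGIN = 3.0      # units above background counted as "cell" for fronts


def contrast_stretch(
    stack: TimeLapseStack,
    low_percentile: float = 1.0,
    high_percentile: float = 99.0,
) -> TimeLapseStack:
    """Linear contrast stretch pushing camera background to the lowest grey levels.

    One linear map (low anchor -> 0, high anchor -> 255) is fitted on the
    whole stack and applied identically to every frame, so the map is
    monotone and frames remain mutually comparable.  A constant stack is
    returned unchanged with a warning.
    """
    frames = stack.frames.astype(float)
    lo = np.percentile(frames, low_percentile)
    hi = np.percentile(frames, high_percentile)
    if hi <= lo:
        warnings.warn("constant stack: contrast stretch is the identity")
        return TimeLapseStack(
            stack.frames.copy(),
            frame_interval=stack.frame_interval,
            t_start=stack.t_start,
            pixel_size=stack.pixel_size,
        )
    out = np.clip((frames - lo) * (255.0 / (hi - lo)), 0, 255)
    return TimeLapseStack(
        np.rint(out).astype(np.uint8),
        frame_interval=stack.frame_interval,
        t_start=stack.t_start,
        pixel_size=stack.pixel_size,
    )


def estimate_background(frame: np.ndarray, embryo_mask: np.ndarray | None = None) -> float:
    """Modal intensity of the pixels outside the embryo mask.

    The mode (of the rounded grey levels) is used rather than the mean
    because it is insensitive to bright foreground pixels that leak into
    the background region.
    """
    frame = np.asarray(frame)
    if frame.size == 0:
        raise ValueError("empty frame")
    values = frame[~embryo_mask] if embryo_mask is not None else frame.ravel()
    if values.size == 0:
        raise ValueError("embryo mask covers the whole frame")
    ints = np.rint(values).astype(int)
    ints -= ints.min()
    return float(np.argmax(np.bincount(ints.ravel())) + np.rint(values).min())


def leading_edge_roi_mean(frame: np.ndarray, roi: CellROI, box_px: int = BOX_PX) -> float:
    """Mean intensity of a ``box_px`` square anchored at the leading edge.

    The box is centred on the midpoint of the ROI's leading-edge segment and
    extends dorsally (upward) from it, covering roughly a third of the
    ventral-dorsal length of a leading cell.
    """
    frame = np.asarray(frame, dtype=float)
    (r0, c0), (r1, c1) = roi.leading_edge
    mid_col = int(round((c0 + c1) / 2.0))
    edge_row = int(round((r0 + r1) / 2.0))
    top = edge_row - box_px + 1
    left = mid_col - box_px // 2
    right = left + box_px
    if top < 0 or left < 0 or right > frame.shape[1] or edge_row >= frame.shape[0]:
        raise ValueError(
            f"cell {roi.cell_id}: {box_px}x{box_px} leading-edge box exceeds frame bounds"
        )
    return float(frame[top : edge_row + 1, left:right].mean())


def cell_mean(frame: np.ndarray, roi: CellROI) -> float:
    """Mean intensity over the whole footprint polygon."""
    mask = roi.footprint_mask(np.asarray(frame).shape)
    return float(np.asarray(frame, dtype=float)[mask].mean())


def extract_vd_profile(
    frame: np.ndarray, roi: CellROI, pixel_size: float = 1.0
) -> LineProfile:
    """Sample intensities along the ventral->dorsal axis at 1 px steps.

    Bilinear interpolation; position 0 is the ventral end of the axis.
    """
    frame = np.asarray(frame, dtype=float)
    (rv, cv), (rd, cd) = roi.axis
    length = float(np.hypot(rd - rv, cd - cv))
    n = int(round(length)) + 1
    if n < 2:
        raise ValueError(f"cell {roi.cell_id}: axis shorter than 2 px")
    t = np.linspace(0.0, 1.0, n)
    rows = rv + t * (rd - rv)
    cols = cv + t * (cd - cv)
    values = ndi.map_coordinates(frame, np.vstack([rows, cols]), order=1, mode="nearest")
    return LineProfile(values, pixel_size=pixel_size * length / (n - 1))


def detect_peaks(
    profile: LineProfile, background: float, threshold: float = PEAK_THRESHOLD
) -> list:
    """Peaks = maximal contiguous runs at least ``threshold`` units above background.

    The comparison is inclusive (``>= background + threshold``); each run is
    one peak regardless of internal structure, with its apex at the run
    maximum (leftmost sample on ties).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    values = profile.intensities
    above = values >= background + threshold
    peaks = []
    i = 0
    n = len(values)
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            apex = i + int(np.argmax(values[i : j + 1]))
            peaks.append(
                Peak(
                    start=i,
                    stop=j + 1,
                    apex_index=apex,
                    apex_height=float(values[apex]),
                    apex_position_um=apex * profile.pixel_size,
                )
            )
            i = j + 1
        else:
            i += 1
    return peaks


def assign_halves(peaks: list, profile: LineProfile) -> tuple:
    """Assign each peak to the ventral or dorsal half of the cell.

    A peak belongs to the half containing its apex; an apex exactly at the
    midpoint counts as ventral (documented tie rule).  Returns
    ``(ventral_count, dorsal_count)`` and labels the peaks in place.
    """
    mid = profile.cell_length / 2.0
    ventral = dorsal = 0
    for p in peaks:
        if p.apex_position_um <= mid:
            p.half = "ventral"
            ventral += 1
        else:
            p.half = "dorsal"
            dorsal += 1
    return ventral, dorsal


def vd_ratio_over_window(
    stack: TimeLapseStack,
    roi: CellROI,
    start_frame: int,
    n_frames: int = WINDOW_FRAMES,
    background: float | None = None,
    threshold: float = PEAK_THRESHOLD,
) -> VDRatioResult:
    """Pooled ventral:dorsal peak-count ratio over a window of frames.

    Half counts are summed per frame over the window (which should start at
    the leading-edge enrichment onset), then the ventral total is divided by
    the dorsal total.  A zero dorsal total yields an undefined-ratio result,
    not an exception.
    """
    if start_frame < 0 or start_frame + n_frames > stack.n_frames:
        raise ValueError(
            f"window [{start_frame}, {start_frame + n_frames}) outside movie "
            f"of {stack.n_frames} frames"
        )
    if background is None:
        background = estimate_background(stack.frames[start_frame])
    ventral = dorsal = 0
    for f in range(start_frame, start_frame + n_frames):
        profile = extract_vd_profile(stack.frames[f], roi, pixel_size=stack.pixel_size)
        peaks = detect_peaks(profile, background, threshold)
        v, d = assign_halves(peaks, profile)
        ventral += v
        dorsal += d
    return VDRatioResult(n_frames=n_frames, ventral_count=ventral, dorsal_count=dorsal)


def enrichment_offset(
    frame: np.ndarray,
    roi: CellROI,
    pixel_size: float = 0.15,
    background: float | None = None,
    margin: float = FRONT_MARGIN,
) -> float:
    """Distance (µm) from the protrusive front to the intensity apex.

    The front is the ventral-most above-background sample on the
    ventral->dorsal axis; the apex is the profile's global maximum.  The
    result is invariant under uniform intensity scaling of the frame (apex
    and front positions are both scale-free).
    """
    if background is None:
        background = estimate_background(frame)
    profile = extract_vd_profile(frame, roi, pixel_size=pixel_size)
    above = profile.intensities > background + margin
    if not above.any():
        raise ValueError(f"cell {roi.cell_id}: no above-background pixel on the axis")
    front_idx = int(np.argmax(above))  # position 0 is the ventral end
    apex_idx = int(np.argmax(profile.intensities))
    return (apex_idx - front_idx) * profile.pixel_size
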