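"""Protrusion lifetime tracking and morphogenetic event timing.

Protrusions are scored geometrically: per frame, the cell front is the
median ventral-most above-background row over the cell's columns, and any
connected above-background component reaching at least ``min_extent_px``
ventral of that front is a protrusion instance.  Instances in consecutive
frames with overlapping column footprints are linked into one track; a
single frame of absence ends the track (retraction is scored at first
absence).

Four events are timed: first pocket-cell protrusion, leading-edge actin
enrichment in the Leading Cells, first Leading-Cell protrusion, and the
ventral meeting of the Leading Cells (front crossing a configured meeting
line in this lateral-view simplification).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .core import ROLE_LEADING, ROLE_POCKET, CellROI, TimeLapseStack
from .polarization import (
    FRONT_MARGIN,
    cell_mean,
    estimate_background,
    leading_edge_roi_mean,
)

_EIGHT_CONN = np.ones((3, 3), dtype=bool)


@dataclass
class ProtrusionTrack:
    """One protrusion from first appearance to retraction."""

    cell_id: str
    first_frame: int
    last_frame: int
    frame_interval: float
    max_extent_um: float
    censored: bool = False  # touches the first or last frame of the movie

    def __post_init__(self) -> None:
        if self.first_frame > self.last_frame:
            raise ValueError("first_frame must be <= last_frame")

    @property
    def duration(self) -> float:
        """Minutes; a protrusion seen in one frame lasts one frame interval."""
        return (self.last_frame - self.first_frame + 1) * self.frame_interval


@dataclass
class EventTimeline:
    """Detected event times in minutes after first cleavage (None = missing)."""

    t_pocket_protrusion: float | None = None
    t_lc_enrichment: float | None = None
    t_lc_protrusion: float | None = None
    t_lc_meeting: float | None = None

    def to_dict(self) -> dict:
        return {
            "t_pocket_protrusion": self.t_pocket_protrusion,
            "t_lc_enrichment": self.t_lc_enrichment,
            "t_lc_protrusion": self.t_lc_protrusion,
            "t_lc_meeting": self.t_lc_meeting,
        }


def detect_front(
    frame: np.ndarray,
    roi: CellROI,
    background: float,
    margin: float = FRONT_MARGIN,
) -> int | None:
    """Median ventral-most above-background row over the cell's columns.

    The median makes the front estimate robust to the minority of columns
    occupied by protrusion fingers or stray noise.  Returns None when no
    column contains cell signal.
    """
    frame = np.asarray(frame, dtype=float)
    lo, hi = roi.column_span
    sub = frame[:, lo:hi] > background + margin
    any_col = sub.any(axis=0)
    if not any_col.any():
        return None
    # ventral-most True row per column = last row index where mask holds
    h = sub.shape[0]
    last_true = h - 1 - np.argmax(sub[::-1, :], axis=0)
    return int(round(float(np.median(last_true[any_col]))))


def detect_protrusions(
    stack: TimeLapseStack,
    roi: CellROI,
    min_extent_px: int = 3,
    background: float | None = None,
    margin: float = FRONT_MARGIN,
) -> list:
    """Detect and link protrusion tracks for one cell.

    Per frame, connected components of above-background pixels extending at
    least ``min_extent_px`` beyond the detected front (ventral direction)
    are protrusion instances; instances in consecutive frames whose column
    ranges overlap continue the same track.
    """
    if background is None:
        background = estimate_background(stack.frames[0])
    lo, hi = roi.column_span
    tracks: list = []
    open_tracks: list = []  # [track_dict]
    for f in range(stack.n_frames):
        frame = np.asarray(stack.frames[f], dtype=float)
        front = detect_front(frame, roi, background, margin)
        instances = []
        if front is not None and front + min_extent_px < frame.shape[0]:
            beyond = frame[front + 1 :, lo:hi] > background + margin
            labels, n_lab = ndi.label(beyond, structure=_EIGHT_CONN)
            for lab in range(1, n_lab + 1):
                rows, cols = np.nonzero(labels == lab)
                extent = int(rows.max()) + 1  # rows are offsets below the front
                # a protrusion is attached to the front (offset 0); detached
                # components are stray noise, not cell protrusions
                if rows.min() == 0 and extent >= min_extent_px:
                    instances.append(
                        {
                            "cols": (int(cols.min()) + lo, int(cols.max()) + lo),
                            "extent_px": extent,
                        }
                    )
        matched = set()
        still_open = []
        for tr in open_tracks:
            hit = None
            for k, inst in enumerate(instances):
                if k in matched:
                    continue
                if inst["cols"][0] <= tr["cols"][1] and tr["cols"][0] <= inst["cols"][1]:
                    hit = k
                    break
            if hit is not None:
                matched.add(hit)
                inst = instances[hit]
                tr["last_frame"] = f
                tr["cols"] = inst["cols"]
                tr["max_extent"] = max(tr["max_extent"], inst["extent_px"])
                still_open.append(tr)
            else:
                tracks.append(tr)
        for k, inst in enumerate(instances):
            if k not in matched:
                still_open.append(
                    {
                        "first_frame": f,
                        "last_frame": f,
                        "cols": inst["cols"],
                        "max_extent": inst["extent_px"],
                    }
                )
        open_tracks = still_open
    tracks.extend(open_tracks)
    tracks.sort(key=lambda tr: (tr["first_frame"], tr["cols"]))
    return [
        ProtrusionTrack(
            cell_id=roi.cell_id,
            first_frame=tr["first_frame"],
            last_frame=tr["last_frame"],
            frame_interval=stack.frame_interval,
            max_extent_um=tr["max_extent"] * stack.pixel_size,
            censored=tr["first_frame"] == 0 or tr["last_frame"] == stack.n_frames - 1,
        )
        for tr in tracks
    ]


def mean_protrusion_duration(tracks: list, include_censored: bool = False) -> tuple:
    """Arithmetic mean and SEM of track durations, in minutes.

    Tracks touching the movie boundaries are right/left-censored (their true
    lifetime is unknown) and excluded by default.
    """
    kept = [t for t in tracks if include_censored or not t.censored]
    if not kept:
        raise ValueError("no (uncensored) protrusion tracks to average")
    durations = np.array([t.duration for t in kept], dtype=float)
    mean = float(durations.mean())
    sem = (
        float(durations.std(ddof=1) / np.sqrt(len(durations)))
        if len(durations) > 1
        else float("nan")
    )
    return mean, sem


def detect_events(
    stack: TimeLapseStack,
    rois: list,
    enrichment_factor: float = 1.2,
    meeting_line_px: int | None = None,
    background: float | None = None,
    margin: float = FRONT_MARGIN,
    min_extent_px: int = 3,
) -> EventTimeline:
    """Time the four actin-dependent morphogenetic events.

    * pocket protrusion onset: first frame with any pocket-cell protrusion;
    * LC enrichment: first frame where the leading-edge box mean reaches
      ``enrichment_factor`` x the whole-cell mean for a Leading Cell;
    * LC protrusion onset: first frame with a Leading-Cell protrusion;
    * LC meeting: first frame where every Leading-Cell front has reached
      ``meeting_line_px`` (skipped when no meeting line is configured).

    Missing events are left as None, never raised.
    """
    if background is None:
        background = estimate_background(stack.frames[0])
    pockets = [r for r in rois if r.role == ROLE_POCKET]
    leaders = [r for r in rois if r.role == ROLE_LEADING]
    if not leaders:
        raise ValueError("need at least one leading-cell ROI")

    def _first_track_frame(cells: list) -> int | None:
        firsts = []
        for roi in cells:
            for tr in detect_protrusions(
                stack, roi, min_extent_px=min_extent_px, background=background, margin=margin
            ):
                firsts.append(tr.first_frame)
        return min(firsts) if firsts else None

    timeline = EventTimeline()
    f = _first_track_frame(pockets) if pockets else None
    if f is not None:
        timeline.t_pocket_protrusion = stack.time_of(f)
    f = _first_track_frame(leaders)
    if f is not None:
        timeline.t_lc_protrusion = stack.time_of(f)

    for f in range(stack.n_frames):
        frame = stack.frames[f]
        if any(
            leading_edge_roi_mean(frame, roi) >= enrichment_factor * cell_mean(frame, roi)
            for roi in leaders
        ):
            timeline.t_lc_enrichment = stack.time_of(f)
            break

    if meeting_line_px is not None:
        for f in range(stack.n_frames):
            fronts = [detect_front(stack.frames[f], roi, background, margin) for roi in leaders]
            if all(fr is not None and fr >= meeting_line_px for fr in fronts):
                timeline.t_lc_meeting = stack.time_of(f)
                break
    return timeline


def event_intervals(timeline: EventTimeline) -> dict:
    """Event times re-expressed as minutes since pocket-protrusion onset."""
    t0 = timeline.t_pocket_protrusion
    if t0 is None:
        raise ValueError("t_pocket_protrusion (time zero) is missing")
    out = {}
    for name, t in timeline.to_dict().items():
        out[name] = None if t is None else t - t0
    return out
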