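"""Standard-format I/O, run configuration, and the end-to-end pipeline.

Movies travel as multi-page uint8 TIFF with a JSON metadata sidecar
(``<stem>.meta.json``: frame_interval, t_start, pixel_size) — TIFF tag
conventions for time and calibration vary too much to rely on.  ROIs are a
JSON list of polygons with axis and leading-edge segments; ground truth a
JSON sidecar.  ``run_pipeline`` ties the stages together
(simulate -> quantify -> events -> protrusions -> stats) and writes a
reproducibility manifest with SHA-256 digests of every output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .core import ROLE_LEADING, CellROI, TimeLapseStack
from .polarization import (
    BOX_PX,
    PEAK_THRESHOLD,
    WINDOW_FRAMES,
    assign_halves,
    detect_peaks,
    enrichment_offset,
    estimate_background,
    extract_vd_profile,
    leading_edge_roi_mean,
    vd_ratio_over_window,
)
from .protrusions import detect_events, detect_protrusions, mean_protrusion_duration
from .simulate import GroundTruth, MovieSpec, builtin_presets, generate_movie

log = logging.getLogger("epiactin")

DEFAULT_FRAME_INTERVAL = 2.0   # minutes
DEFAULT_T_START = 240.0        # minutes after first cleavage
DEFAULT_PIXEL_SIZE = 0.15      # µm / px


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _meta_path(path: Path) -> Path:
    return path.with_name(path.stem + ".meta.json")


def save_stack(path, stack: TimeLapseStack) -> None:
    """Write a multi-page uint8 TIFF plus its metadata sidecar."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(stack.frames, dtype=np.uint8))
    meta = {
        "frame_interval": stack.frame_interval,
        "t_start": stack.t_start,
        "pixel_size": stack.pixel_size,
    }
    _meta_path(path).write_text(json.dumps(meta, indent=1, sort_keys=True))


def load_stack(
    path,
    frame_interval: float | None = None,
    t_start: float | None = None,
    pixel_size: float | None = None,
) -> TimeLapseStack:
    """Read a multi-page TIFF; metadata from sidecar, kwargs, or defaults.

    Explicit keyword arguments override the sidecar; when neither is
    available the documented defaults (2 min, 240 min, 0.15 µm/px) are used
    with a warning.
    """
    path = Path(path)
    try:
        frames = tifffile.imread(path)
    except Exception as exc:  # unreadable / empty / truncated file
        raise ValueError(f"cannot read TIFF stack {path}: {exc}") from exc
    frames = np.asarray(frames)
    if frames.ndim == 2:
        frames = frames[None, ...]
    if frames.ndim != 3 or frames.dtype == object:
        raise ValueError(f"{path}: frames have mixed shapes or wrong dimensionality")
    meta = {}
    mp = _meta_path(path)
    if mp.exists():
        meta = json.loads(mp.read_text())
    else:
        warnings.warn(
            f"no metadata sidecar for {path.name}; using defaults "
            f"({DEFAULT_FRAME_INTERVAL} min, {DEFAULT_T_START} min, "
            f"{DEFAULT_PIXEL_SIZE} µm/px)"
        )
    return TimeLapseStack(
        frames,
        frame_interval=(
            frame_interval if frame_interval is not None
            else meta.get("frame_interval", DEFAULT_FRAME_INTERVAL)
        ),
        t_start=t_start if t_start is not None else meta.get("t_start", DEFAULT_T_START),
        pixel_size=(
            pixel_size if pixel_size is not None
            else meta.get("pixel_size", DEFAULT_PIXEL_SIZE)
        ),
    )


def save_rois(path, rois: list, meeting_line_px: int | None = None) -> None:
    data = {
        "meeting_line_px": meeting_line_px,
        "cells": [
            {
                "cell_id": r.cell_id,
                "role": r.role,
                "polygon": r.polygon.tolist(),
                "axis": r.axis.tolist(),
                "leading_edge": r.leading_edge.tolist(),
            }
            for r in rois
        ],
    }
    Path(path).write_text(json.dumps(data, indent=1, sort_keys=True))


def load_rois(path) -> tuple:
    """Returns (rois, meeting_line_px)."""
    data = json.loads(Path(path).read_text())
    rois = [
        CellROI(
            cell_id=c["cell_id"],
            role=c["role"],
            polygon=np.asarray(c["polygon"]),
            axis=np.asarray(c["axis"]),
            leading_edge=np.asarray(c["leading_edge"]),
        )
        for c in data["cells"]
    ]
    return rois, data.get("meeting_line_px")


def save_ground_truth(path, gt: GroundTruth) -> None:
    Path(path).write_text(json.dumps(gt.to_dict(), indent=1, sort_keys=True))


def load_ground_truth(path) -> GroundTruth:
    return GroundTruth.from_dict(json.loads(Path(path).read_text()))


@dataclass
class RunConfig:
    """Everything needed to reproduce a pipeline run.

    Threshold defaults are the printed measurement constants: a 10-unit peak
    threshold, a 36-px leading-edge box, and a 20-frame (40-minute) ratio
    window.
    """

    outdir: str = "epiactin-out"
    preset: str | None = "wild_type"      # simulate stage; None = use stack_path
    stack_path: str | None = None
    rois_path: str | None = None
    seed: int = 0
    noise_sigma: float | None = None      # None = generator default
    peak_threshold: float = PEAK_THRESHOLD
    box_px: int = BOX_PX
    window_frames: int = WINDOW_FRAMES
    enrichment_factor: float = 1.2
    start_frame: str | int = "auto"       # 'auto' = enrichment-onset frame
    verbosity: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute simulate (optional) -> quantify -> events -> protrusions -> stats.

    Writes per-cell quantitation CSV, protrusion-track CSV, event-timeline
    JSON, a summary JSON and a reproducibility manifest into
    ``config.outdir`` and returns the result bundle.  Any stage failure is
    re-raised as a :class:`StageError` naming the stage.
    """
    logging.basicConfig(level=getattr(logging, config.verbosity, logging.INFO))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list = []

    # --- simulate -----------------------------------------------------------
    meeting_line = None
    try:
        if config.preset is not None:
            presets = builtin_presets()
            if config.preset not in presets:
                raise ValueError(
                    f"unknown preset {config.preset!r}; available: {sorted(presets)}"
                )
            spec_kwargs = {"preset": presets[config.preset], "seed": config.seed}
            if config.noise_sigma is not None:
                spec_kwargs["noise_sigma"] = config.noise_sigma
            spec = MovieSpec(**spec_kwargs)
            stack, gt, rois = generate_movie(spec)
            meeting_line = gt.meeting_line_px
            stack_path = outdir / "movie.tif"
            save_stack(stack_path, stack)
            save_rois(outdir / "movie.rois.json", rois, meeting_line)
            save_ground_truth(outdir / "movie.truth.json", gt)
            written += [stack_path, _meta_path(stack_path),
                        outdir / "movie.rois.json", outdir / "movie.truth.json"]
            log.info("simulate: preset=%s seed=%d -> %s", config.preset,
                     config.seed, stack_path)
        else:
            if config.stack_path is None or config.rois_path is None:
                raise ValueError("need stack_path and rois_path when no preset is set")
            stack = load_stack(config.stack_path)
            rois, meeting_line = load_rois(config.rois_path)
    except StageError:
        raise
    except Exception as exc:
        raise StageError("simulate", str(exc)) from exc

    # --- quantify -----------------------------------------------------------
    try:
        background = estimate_background(stack.frames[0])
        log.info("quantify: background=%.1f threshold=%.1f box=%dpx window=%d frames",
                 background, config.peak_threshold, config.box_px, config.window_frames)
        leaders = [r for r in rois if r.role == ROLE_LEADING]
        rows = []
        for roi in leaders:
            for f in range(stack.n_frames):
                frame = stack.frames[f]
                profile = extract_vd_profile(frame, roi, pixel_size=stack.pixel_size)
                peaks = detect_peaks(profile, background, config.peak_threshold)
                v, d = assign_halves(peaks, profile)
                rows.append(
                    {
                        "cell_id": roi.cell_id,
                        "frame": f,
                        "t_min": stack.time_of(f),
                        "roi_mean": leading_edge_roi_mean(frame, roi, config.box_px),
                        "ventral_count": v,
                        "dorsal_count": d,
                    }
                )
        quantify_df = pd.DataFrame(rows)
        quantify_path = outdir / "quantify.csv"
        quantify_df.to_csv(quantify_path, index=False)
        written.append(quantify_path)
    except Exception as exc:
        raise StageError("quantify", str(exc)) from exc

    # --- events -------------------------------------------------------------
    try:
        timeline = detect_events(
            stack, rois,
            enrichment_factor=config.enrichment_factor,
            meeting_line_px=meeting_line,
            background=background,
        )
        events_path = outdir / "events.json"
        events_path.write_text(json.dumps(timeline.to_dict(), indent=1, sort_keys=True))
        written.append(events_path)
        log.info("events: %s", timeline.to_dict())
    except Exception as exc:
        raise StageError("events", str(exc)) from exc

    # --- protrusions --------------------------------------------------------
    try:
        tracks = []
        for roi in rois:
            tracks += detect_protrusions(stack, roi, background=background)
        track_df = pd.DataFrame(
            [
                {
                    "cell_id": t.cell_id,
                    "first_frame": t.first_frame,
                    "last_frame": t.last_frame,
                    "duration_min": t.duration,
                    "max_extent_um": t.max_extent_um,
                    "censored": t.censored,
                }
                for t in tracks
            ]
        )
        tracks_path = outdir / "protrusions.csv"
        track_df.to_csv(tracks_path, index=False)
        written.append(tracks_path)
    except Exception as exc:
        raise StageError("protrusions", str(exc)) from exc

    # --- stats --------------------------------------------------------------
    try:
        if config.start_frame == "auto":
            if timeline.t_lc_enrichment is not None:
                start_frame = stack.frame_at_or_after(timeline.t_lc_enrichment)
            else:
                start_frame = 0
        else:
            start_frame = int(config.start_frame)
        summary: dict = {"background": background, "start_frame": start_frame}
        ratios = {}
        offsets = {}
        for roi in leaders:
            res = vd_ratio_over_window(
                stack, roi, start_frame,
                n_frames=config.window_frames,
                background=background,
                threshold=config.peak_threshold,
            )
            ratios[roi.cell_id] = {
                "ventral": res.ventral_count,
                "dorsal": res.dorsal_count,
                "ratio": res.ratio,
            }
            try:
                offsets[roi.cell_id] = enrichment_offset(
                    stack.frames[start_frame], roi,
                    pixel_size=stack.pixel_size, background=background,
                )
            except ValueError:
                offsets[roi.cell_id] = None
        summary["vd_ratio"] = ratios
        summary["enrichment_offset_um"] = offsets
        try:
            mean_dur, sem_dur = mean_protrusion_duration(tracks)
            summary["mean_protrusion_duration_min"] = mean_dur
            summary["protrusion_duration_sem_min"] = sem_dur
        except ValueError:
            summary["mean_protrusion_duration_min"] = None
            summary["protrusion_duration_sem_min"] = None
        summary["events"] = timeline.to_dict()
        summary_path = outdir / "summary.json"
        summary_path.write_text(json.dumps(summary, indent=1, sort_keys=True))
        written.append(summary_path)
    except Exception as exc:
        raise StageError("stats", str(exc)) from exc

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "outputs": {p.name: _sha256(p) for p in sorted(written)},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return {
        "stack": stack,
        "rois": rois,
        "timeline": timeline,
        "tracks": tracks,
        "quantify": quantify_df,
        "summary": summary,
        "manifest": manifest,
    }
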