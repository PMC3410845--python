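"""Seeded synthetic data with known ground truth.

The movie generator emulates the statistical structure of lateral-view
time-lapse recordings of an F-actin reporter in the migrating embryonic
epidermis: a horizontal band of epidermal cells (dorsal up), two Leading
Cells (LCs) plus a pocket cell, punctate intensity peaks placed along each
cell's ventral-dorsal axis with a configurable ventral fraction, a bright
leading-edge ridge offset dorsally behind the protrusive front, and
finger-shaped protrusions beyond the front whose integer frame-lifetimes
follow a two-point distribution calibrated to a target mean duration.

Everything placed is recorded in a :class:`GroundTruth` sidecar so that the
measurement modules can be validated pixel-for-pixel.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np

from .core import (
    ROLE_LEADING,
    ROLE_OTHER,
    ROLE_POCKET,
    CellROI,
    LineProfile,
    TimeLapseStack,
)

# ---------------------------------------------------------------------------
# presets


@dataclass(frozen=True)
class GenotypePreset:
    """Per-genotype constants driving the synthetic movie.

    Event times are minutes after first cleavage; ``None`` means the event
    never happens for that genotype (e.g. the LCs of gex-3 embryos never
    meet and never enrich actin at the leading edge).
    """

    name: str
    t_pocket_protrusion: float
    t_lc_enrichment: float | None
    t_lc_protrusion: float | None
    t_lc_meeting: float | None
    mean_protrusion_duration: float  # minutes
    ventral_peak_fraction: float     # probability a punctum lands ventrally
    peak_rate: float                 # expected puncta per cell per frame
    enrichment_offset: float         # µm, ridge sits this far dorsal of the front
    baseline_intensity_scale: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.ventral_peak_fraction <= 1.0):
            raise ValueError("ventral_peak_fraction must be in [0, 1]")
        if self.mean_protrusion_duration <= 0:
            raise ValueError("mean_protrusion_duration must be positive")
        if self.peak_rate < 0:
            raise ValueError("peak_rate must be >= 0")
        times = [
            self.t_pocket_protrusion,
            self.t_lc_enrichment,
            self.t_lc_protrusion,
            self.t_lc_meeting,
        ]
        defined = [t for t in times if t is not None]
        if any(b < a for a, b in zip(defined, defined[1:])):
            raise ValueError("event times must be non-decreasing where defined")


def builtin_presets() -> dict:
    """Built-in genotype presets.

    Event schedules and protrusion lifetimes are the published wild-type and
    mutant constants (pocket protrusion onset 250 min, wild-type LC meeting
    320 min, mean protrusion lifetimes 2.5 / 9 / 6 / 6 min for wild type,
    gex-3, sax-3 and vab-1; leading-edge enrichment at ~260 / ~270 / ~260 /
    ~275 / ~270 min for wild type / unc-40 / unc-6 / sax-3 / vab-1).  Peak
    rates and ventral fractions are free parameters of the simulation chosen
    to preserve the qualitative ordering of ventral polarization
    (vab-1 < sax-3 < wild type); no numeric values are published for them.
    """
    presets = [
        GenotypePreset("wild_type", 250, 260, 262, 320, 2.5, 0.75, 2.0, 2.0, 1.0),
        GenotypePreset("gex-3", 250, None, None, None, 9.0, 0.50, 0.8, 2.0, 0.8),
        GenotypePreset("unc-40", 250, 270, 272, 340, 3.0, 0.65, 1.5, 2.0, 0.9),
        GenotypePreset("unc-6", 250, 260, 262, 340, 3.0, 0.65, 1.5, 2.0, 0.9),
        GenotypePreset("sax-3", 250, 275, 277, 350, 6.0, 0.60, 1.2, 2.0, 0.9),
        GenotypePreset("vab-1", 250, 270, 272, 350, 6.0, 0.55, 1.8, 2.0, 1.2),
    ]
    return {p.name: p for p in presets}


@dataclass
class MovieSpec:
    """Full specification of one synthetic movie."""

    preset: GenotypePreset
    height: int = 180
    width: int = 200
    pixel_size: float = 0.15      # µm / px
    frame_interval: float = 2.0   # minutes
    t_start: float = 240.0        # minutes after first cleavage
    n_frames: int = 45
    background_level: float = 12.0  # fluorescent units
    noise_sigma: float = 1.0        # additive Gaussian, fluorescent units
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.background_level < 0:
            raise ValueError("background_level must be >= 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.height <= 0 or self.width <= 0 or self.pixel_size <= 0:
            raise ValueError("all dimensions must be positive")
        if self.preset.mean_protrusion_duration < self.frame_interval:
            raise ValueError(
                "mean_protrusion_duration shorter than the frame interval "
                "cannot be realized at this sampling rate"
            )


# ---------------------------------------------------------------------------
# fixed lateral-view geometry (pixel units, defaults sized for 180x200)

_BAND_TOP = 20          # dorsal boundary row of the epidermal band
_CELL_HEIGHT = 106      # ventral-dorsal extent of a cell before migration
_ADVANCE_PX = 34        # LC front travel from protrusion onset to meeting
_MAX_FINGER_EXT = 6     # longest protrusion finger, px beyond the front
_SLOT_STEP = 6          # column spacing between protrusion slots
_SPAWN_PROB = 0.2       # per free slot per frame
_PUNCTUM_MIN_SEP = 5    # rows between puncta on one axis, one frame
_MIDLINE_GUARD = 3      # puncta stay this many rows off the half-way line

# intensity increments above background, scaled by baseline_intensity_scale
_BODY_AMP = 5.0                  # cytoplasmic F-actin, below the peak threshold
_PUNCTUM_AMP = (25.0, 17.0)      # punctum centre / 4-neighbour shoulders
_RIDGE_AMP = (200.0, 140.0)      # ridge centre row / flanking rows
_FINGER_AMP = 20.0               # protrusion fingers are actin-rich


@dataclass
class _CellGeom:
    cell_id: str
    role: str
    col_lo: int
    col_hi: int  # exclusive

    @property
    def axis_col(self) -> int:
        return (self.col_lo + self.col_hi) // 2


def _default_cells(width: int) -> list:
    if width < 195:
        raise ValueError("movie width must be >= 195 px for the default cell layout")
    return [
        _CellGeom("LC-1", ROLE_LEADING, 10, 60),
        _CellGeom("LC-2", ROLE_LEADING, 70, 120),
        _CellGeom("pocket-1", ROLE_POCKET, 130, 190),
    ]


@dataclass
class GroundTruth:
    """Everything the generator placed, for validating the measurements.

    ``peaks[frame]`` lists ``(cell_id, row, half, kind)`` for every
    supra-threshold region on a cell's ventral-dorsal axis; ``kind`` is
    ``"punctum"`` for the stochastic puncta and ``"ridge"`` for the
    deterministic leading-edge enrichment ridge (which the peak detector
    correctly counts as a ventral region).
    """

    event_times: dict = field(default_factory=dict)
    protrusion_table: list = field(default_factory=list)  # dicts, see generate_movie
    peaks: dict = field(default_factory=dict)             # frame -> list of tuples
    front: dict = field(default_factory=dict)             # cell_id -> list of rows
    meeting_line_px: int | None = None
    midline_row: float | None = None

    def vd_counts(
        self,
        start_frame: int,
        n_frames: int,
        cell_ids: list | None = None,
        include_ridge: bool = False,
    ) -> tuple:
        """Placed (ventral, dorsal) peak counts over a window of frames."""
        v = d = 0
        for f in range(start_frame, start_frame + n_frames):
            for cell_id, _row, half, kind in self.peaks.get(f, []):
                if cell_ids is not None and cell_id not in cell_ids:
                    continue
                if kind == "ridge" and not include_ridge:
                    continue
                if half == "ventral":
                    v += 1
                else:
                    d += 1
        return v, d

    def vd_ratio(self, start_frame: int, n_frames: int, **kw) -> float | None:
        v, d = self.vd_counts(start_frame, n_frames, **kw)
        return None if d == 0 else v / d

    def to_dict(self) -> dict:
        return {
            "event_times": self.event_times,
            "protrusion_table": self.protrusion_table,
            "peaks": {str(f): [list(p) for p in v] for f, v in self.peaks.items()},
            "front": {k: list(map(int, v)) for k, v in self.front.items()},
            "meeting_line_px": self.meeting_line_px,
            "midline_row": self.midline_row,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        gt = cls()
        gt.event_times = {k: v for k, v in d.get("event_times", {}).items()}
        gt.protrusion_table = d.get("protrusion_table", [])
        gt.peaks = {
            int(f): [tuple(p) for p in v] for f, v in d.get("peaks", {}).items()
        }
        gt.front = {k: list(v) for k, v in d.get("front", {}).items()}
        gt.meeting_line_px = d.get("meeting_line_px")
        gt.midline_row = d.get("midline_row")
        return gt


def _lifetime_frames(mean_minutes: float, frame_interval: float, rng) -> int:
    """Two-point lifetime on consecutive frame counts, exact in expectation."""
    m = mean_minutes / frame_interval
    lo = math.floor(m)
    hi = math.ceil(m)
    if lo == hi:
        return lo
    return hi if rng.random() < (m - lo) else lo


def _event_frame(t: float | None, spec: MovieSpec) -> int | None:
    """First frame index at/after an event time, or None if unscheduled/late."""
    if t is None:
        return None
    f = max(0, int(math.ceil((t - spec.t_start) / spec.frame_interval - 1e-9)))
    return f if f < spec.n_frames else None


def generate_movie(spec: MovieSpec):
    """Render a synthetic enclosure movie.

    Returns
    -------
    (stack, ground_truth, rois)
        ``stack`` is a uint8 :class:`TimeLapseStack`; ``ground_truth`` a
        :class:`GroundTruth` recording every placed structure; ``rois`` the
        list of :class:`CellROI` (two leading cells, one pocket cell) with
        footprints at the pre-migration cell extent.
    """
    preset = spec.preset
    rng = np.random.default_rng(spec.seed)
    cells = _default_cells(spec.width)

    band_top = _BAND_TOP
    front0 = band_top + _CELL_HEIGHT
    meeting_row = front0 + _ADVANCE_PX
    if spec.height < meeting_row + _MAX_FINGER_EXT + 4:
        raise ValueError("movie height too small for the default geometry")
    midline_row = (band_top + front0) / 2.0
    scale = preset.baseline_intensity_scale
    offset_px = int(round(preset.enrichment_offset / spec.pixel_size))

    f_pocket = _event_frame(preset.t_pocket_protrusion, spec)
    f_enrich = _event_frame(preset.t_lc_enrichment, spec)
    f_lc_prot = _event_frame(preset.t_lc_protrusion, spec)
    # the meeting frame is schedulable even if it falls beyond the movie
    if preset.t_lc_meeting is None or preset.t_lc_protrusion is None:
        f_meet_sched = None
    else:
        f_meet_sched = int(
            math.ceil((preset.t_lc_meeting - spec.t_start) / spec.frame_interval - 1e-9)
        )

    gt = GroundTruth(meeting_line_px=meeting_row, midline_row=midline_row)

    # --- front schedule per cell -------------------------------------------
    fronts = {}
    for cell in cells:
        rows = np.full(spec.n_frames, front0, dtype=int)
        if cell.role == ROLE_LEADING and f_lc_prot is not None and f_meet_sched is not None:
            n_steps = max(1, f_meet_sched - f_lc_prot)
            for f in range(spec.n_frames):
                k = min(max(0, f - f_lc_prot), n_steps)
                rows[f] = front0 + (_ADVANCE_PX * k) // n_steps
        fronts[cell.cell_id] = rows
        gt.front[cell.cell_id] = list(rows)

    # --- protrusion schedule ------------------------------------------------
    # fixed 2-px-wide column slots with >= 4 px gaps; one active finger per
    # slot, one-frame refractory gap after retraction, so tracks never touch
    onset = {}
    for cell in cells:
        onset[cell.cell_id] = f_pocket if cell.role == ROLE_POCKET else f_lc_prot
    slots = {
        cell.cell_id: [
            (c, c + 2) for c in range(cell.col_lo + 2, cell.col_hi - 3, _SLOT_STEP)
        ]
        for cell in cells
    }
    # per-slot state: frames remaining / cooldown
    active = {cid: [None] * len(s) for cid, s in slots.items()}   # (end_frame, ext)
    cooldown = {cid: [0] * len(s) for cid, s in slots.items()}
    finger_pixels = {}  # frame -> list of (cell_id, col_lo, col_hi, ext)
    for f in range(spec.n_frames):
        per_frame = []
        for cell in cells:
            cid = cell.cell_id
            start = onset[cid]
            if start is None or f < start:
                continue
            for si, (c0, c1) in enumerate(slots[cid]):
                st = active[cid][si]
                if st is not None and f > st[0]:
                    active[cid][si] = None
                    cooldown[cid][si] = 1
                    st = None
                if st is None:
                    if cooldown[cid][si] > 0:
                        cooldown[cid][si] -= 1
                    else:
                        # force the very first protrusion of a cell so the
                        # event is rendered exactly at its scheduled frame
                        force = f == start and si == 0
                        if force or rng.random() < _SPAWN_PROB:
                            life = _lifetime_frames(
                                preset.mean_protrusion_duration,
                                spec.frame_interval,
                                rng,
                            )
                            ext = int(rng.integers(4, _MAX_FINGER_EXT + 1))
                            last = min(f + life - 1, spec.n_frames - 1)
                            active[cid][si] = (last, ext)
                            gt.protrusion_table.append(
                                {
                                    "cell_id": cid,
                                    "first_frame": f,
                                    "last_frame": last,
                                    "extent_px": ext,
                                    "censored": bool(
                                        f + life - 1 > spec.n_frames - 1
                                    ),
                                }
                            )
                            st = active[cid][si]
                if st is not None:
                    per_frame.append((cid, c0, c1, st[1]))
        finger_pixels[f] = per_frame

    # --- puncta schedule ----------------------------------------------------
    ridge_active = lambda f: f_enrich is not None and f >= f_enrich  # noqa: E731
    puncta = {}  # frame -> list of (cell_id, row)
    v_lo, v_hi = int(midline_row) + _MIDLINE_GUARD, front0 - 2       # ventral rows
    d_lo, d_hi = band_top + 2, int(midline_row) - _MIDLINE_GUARD     # dorsal rows
    for f in range(spec.n_frames):
        placed = []
        gt.peaks[f] = []
        for cell in cells:
            ridge_row = None
            if cell.role == ROLE_LEADING and ridge_active(f):
                ridge_row = int(fronts[cell.cell_id][f]) - offset_px
                gt.peaks[f].append((cell.cell_id, ridge_row, "ventral", "ridge"))
            taken = []
            k = rng.poisson(preset.peak_rate)
            for _ in range(k):
                ventral = rng.random() < preset.ventral_peak_fraction
                lo, hi = (v_lo, v_hi) if ventral else (d_lo, d_hi)
                for _try in range(50):
                    r = int(rng.integers(lo, hi + 1))
                    if ridge_row is not None and abs(r - ridge_row) < 4:
                        continue
                    if all(abs(r - t) >= _PUNCTUM_MIN_SEP for t in taken):
                        taken.append(r)
                        placed.append((cell.cell_id, r))
                        gt.peaks[f].append(
                            (cell.cell_id, r, "ventral" if ventral else "dorsal", "punctum")
                        )
                        break
        puncta[f] = placed

    # --- realized event times ----------------------------------------------
    def _t(frame: int | None) -> float | None:
        return None if frame is None else spec.t_start + frame * spec.frame_interval

    lc_fronts = [fronts[c.cell_id] for c in cells if c.role == ROLE_LEADING]
    f_meet = None
    if lc_fronts and f_meet_sched is not None:
        reached = np.all([fr >= meeting_row for fr in lc_fronts], axis=0)
        hits = np.nonzero(reached)[0]
        f_meet = int(hits[0]) if len(hits) else None
    events = {
        "t_pocket_protrusion": _t(f_pocket),
        "t_lc_enrichment": _t(f_enrich),
        "t_lc_protrusion": _t(f_lc_prot),
        "t_lc_meeting": _t(f_meet),
    }
    gt.event_times = {k: v for k, v in events.items() if v is not None}

    # --- render -------------------------------------------------------------
    axis_col = {c.cell_id: c.axis_col for c in cells}
    movie = np.empty((spec.n_frames, spec.height, spec.width), dtype=np.uint8)
    for f in range(spec.n_frames):
        img = np.full((spec.height, spec.width), spec.background_level, dtype=float)
        for cell in cells:
            fr = int(fronts[cell.cell_id][f])
            img[band_top : fr + 1, cell.col_lo : cell.col_hi] += _BODY_AMP * scale
            if cell.role == ROLE_LEADING and ridge_active(f):
                rr = fr - offset_px
                img[rr, cell.col_lo : cell.col_hi] += (_RIDGE_AMP[0] - _RIDGE_AMP[1]) * scale
                img[rr - 1 : rr + 2, cell.col_lo : cell.col_hi] += _RIDGE_AMP[1] * scale
        for cid, r in puncta[f]:
            c = axis_col[cid]
            img[r, c] += _PUNCTUM_AMP[0] * scale
            img[r - 1, c] += _PUNCTUM_AMP[1] * scale
            img[r + 1, c] += _PUNCTUM_AMP[1] * scale
            img[r, c - 1] += _PUNCTUM_AMP[1] * scale
            img[r, c + 1] += _PUNCTUM_AMP[1] * scale
        for cid, c0, c1, ext in finger_pixels[f]:
            fr = int(fronts[cid][f])
            img[fr + 1 : fr + 1 + ext, c0:c1] += _FINGER_AMP * scale
        if spec.noise_sigma > 0:
            img += rng.normal(0.0, spec.noise_sigma, img.shape)
        movie[f] = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    stack = TimeLapseStack(
        movie,
        frame_interval=spec.frame_interval,
        t_start=spec.t_start,
        pixel_size=spec.pixel_size,
    )

    rois = []
    for cell in cells:
        poly = np.array(
            [
                [band_top, cell.col_lo],
                [band_top, cell.col_hi - 1],
                [front0, cell.col_hi - 1],
                [front0, cell.col_lo],
            ],
            dtype=float,
        )
        rois.append(
            CellROI(
                cell_id=cell.cell_id,
                role=cell.role,
                polygon=poly,
                axis=np.array([[front0, cell.axis_col], [band_top, cell.axis_col]], dtype=float),
                leading_edge=np.array(
                    [[front0, cell.col_lo], [front0, cell.col_hi - 1]], dtype=float
                ),
            )
        )
    return stack, gt, rois


# ---------------------------------------------------------------------------
# small fixture generators


def generate_profile(
    n_positions: int,
    background: float,
    peak_positions: list,
    peak_height: float = 15.0,
    pixel_size: float = 1.0,
) -> LineProfile:
    """A flat profile with single-position spikes of ``background + peak_height``."""
    if len(set(peak_positions)) != len(peak_positions):
        raise ValueError("overlapping peak positions")
    values = np.full(n_positions, float(background))
    for p in peak_positions:
        if not (0 <= p < n_positions):
            raise ValueError(f"peak position {p} outside profile")
        values[p] = background + peak_height
    return LineProfile(values, pixel_size=pixel_size)


def generate_phenotype_counts(
    class_probs,
    n: int,
    seed: int = 0,
    genotype: str = "synthetic",
    temperature: float = 20.0,
):
    """Multinomial draw of (wild-type, Full Gex, Partial Gex) embryo counts."""
    from .stats import PhenotypeCounts

    probs = np.asarray(class_probs, dtype=float)
    if probs.shape != (3,) or not np.isclose(probs.sum(), 1.0):
        raise ValueError("class_probs must be 3 probabilities summing to 1")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    wt, full, partial = rng.multinomial(n, probs)
    return PhenotypeCounts(
        genotype=genotype,
        temperature=temperature,
        n_wildtype=int(wt),
        n_full_gex=int(full),
        n_partial_gex=int(partial),
    )


def generate_blot_series(
    true_ratios,
    control_level: float = 100.0,
    noise_cv: float = 0.0,
    seed: int = 0,
    labels: list | None = None,
):
    """Band/loading-control intensity pairs with known normalized-relative truth.

    The first entry is the reference lane (relative level 1.0).  Noise is
    multiplicative lognormal with coefficient of variation ``noise_cv``,
    applied independently to each band and control reading; at zero noise
    ``normalize_relative`` recovers ``true_ratios`` exactly.
    """
    from .biochem import DensitometryRecord

    ratios = np.asarray(true_ratios, dtype=float)
    if np.any(ratios < 0):
        raise ValueError("ratios must be >= 0")
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(math.log1p(noise_cv**2)) if noise_cv > 0 else 0.0

    def _noisy(x: float) -> float:
        if sigma == 0:
            return x
        return x * math.exp(rng.normal(-sigma**2 / 2, sigma))

    if labels is None:
        labels = ["wild type"] + [f"sample-{i}" for i in range(1, len(ratios))]
    return [
        DensitometryRecord(
            label=lab,
            band_intensity=_noisy(control_level * r),
            control_intensity=_noisy(control_level),
        )
        for lab, r in zip(labels, ratios)
    ]


def generate_fractionation_series(
    fraction_shares,
    total: float = 800.0,
    noise_cv: float = 0.0,
    seed: int = 0,
):
    """Band intensities for the 8 fractions S1,P1..S4,P4 proportional to shares."""
    from .biochem import FractionationSeries

    shares = np.asarray(fraction_shares, dtype=float)
    if shares.shape != (8,):
        raise ValueError("need 8 fraction shares (S1, P1, S2, P2, S3, P3, S4, P4)")
    if np.any(shares < 0):
        raise ValueError("negative shares rejected")
    if not np.isclose(shares.sum(), 1.0):
        raise ValueError("shares must sum to 1")
    rng = np.random.default_rng(seed)
    intensities = shares * total
    if noise_cv > 0:
        intensities = intensities * (1 + rng.normal(0, noise_cv, 8))
        intensities = np.clip(intensities, 0, None)
    return FractionationSeries(intensities=intensities)
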