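# Methods

## The measurement problem

During ventral enclosure the *C. elegans* epidermis migrates over the embryo
surface. In lateral view (dorsal up) the epidermal band sits above a free
ventral margin; each migrating cell has a ventral **leading edge** from which
actin-rich protrusions extend. The quantities of interest are the amount and
ventral polarization of F-actin in the two Leading Cells (LCs), the lifetime
of leading-edge protrusions, and the times of four stereotyped events:
pocket-cell protrusion onset, leading-edge actin enrichment in the LCs, LC
protrusion onset, and LC meeting. All times are minutes after first cleavage;
movies are sampled every 2 minutes starting at 240 minutes by default.

## Synthetic movie model

The generator renders a simplified lateral view on a `180 × 200` px canvas
(0.15 µm/px by default, so a cell's 106-px ventral–dorsal extent is ≈ 16 µm
and a 36-px box is ≈ one third of it):

- **Cell band.** Three rectangular cells (two LCs, one pocket cell) spanning
  rows 20–126, rendered at background + 5 units — above the front-detection
  margin (3 units) but deliberately below the peak threshold (10 units), as
  diffuse cytoplasmic actin is in real movies.
- **Puncta.** Per cell and frame, a Poisson(`peak_rate`) number of bright
  puncta is placed *on the cell's ventral–dorsal axis* (centre +25, shoulders
  +17 units), ventral with probability `ventral_peak_fraction`. Puncta keep
  ≥ 5 rows apart, ≥ 3 rows off the half-way line (no straddling by
  construction) and ≥ 4 rows off the enrichment ridge, so each punctum is
  exactly one supra-threshold run of the profile.
- **Enrichment ridge.** From `t_lc_enrichment` onward each LC carries a
  3-row ridge (centre +200, flanks +140) whose centre sits
  `round(enrichment_offset / pixel_size)` px dorsal of the current front.
  At 0.15 µm/px a 2 µm offset rounds to 13 px, so the measured offset on
  noiseless input is 1.95 µm — within one pixel of the target, the stated
  resolution of the measurement.
- **Protrusions.** Finger-shaped extensions (2 px wide, 4–6 px long,
  +20 units) occupy fixed column slots spaced 6 px apart (≥ 4 px gaps, so
  simultaneous fingers never touch). Integer frame-lifetimes are drawn from
  the two-point distribution on ⌊m⌋/⌈m⌉ frames, `m = mean_duration / Δt`,
  which has mean exactly `m` — continuous lifetimes would bias a count-based
  lifetime measurement at 2-minute sampling. A retracted slot stays empty
  for one frame before reuse, so consecutive occupancies are distinct tracks.
  The first protrusion of a cell is forced at its scheduled onset frame so
  the rendered movie realizes the preset event time exactly.
- **Migration.** LC fronts advance linearly (integer-floored) from
  protrusion onset to the meeting line (34 px below the initial front),
  arriving exactly at the scheduled meeting frame. Pocket cells do not
  migrate in this simplification.
- **Noise.** Additive Gaussian (σ = 1 unit by default) above a constant
  background (12 units), clipped and rounded to uint8. Poisson shot noise,
  photobleaching and camera gain structure are not modelled.

Every placed structure is recorded in a `GroundTruth` sidecar (event times,
protrusion table, per-frame peak rows with half labels and a punctum/ridge
kind tag, per-frame fronts), and recorded event times are, by construction,
the first frames at which the corresponding structures are rendered.

**Preset values.** Event schedules and mean lifetimes are the published
constants (see README). `peak_rate` and `ventral_peak_fraction` have no
published values; the presets expose them as free parameters with the
documented qualitative ordering of ventral polarization
(vab-1 0.55 < sax-3 0.60 < wild type 0.75) rather than inventing precise
numbers. Wild-type defaults (`peak_rate` 2.0/cell/frame, fraction 0.75) give
a few hundred measurable peaks per 20-frame window across both LCs, a
realistic yield for this kind of reporter. `unc-40`/`unc-6` lifetimes use
3.0 min from the published 2.5–3 min range.

## Measurement conventions

- **Background** is the modal grey level outside the embryo mask (whole
  frame if none); the mode is robust to bright foreground. The peak
  criterion is *inclusive*: intensity ≥ background + 10.
- **Peaks** are maximal contiguous supra-threshold runs — one peak per run
  regardless of internal wiggles — with the apex at the run maximum
  (leftmost on ties).
- **Half assignment** is by apex position along the axis; an apex exactly at
  the midpoint counts as ventral (a deterministic, documented tie rule).
- **V:D ratio** sums per-frame half counts over the window (default 20
  frames starting at enrichment onset) before dividing; a zero dorsal total
  yields an undefined-ratio flag, not an exception.
- **Front detection** takes, per column of the cell span, the ventral-most
  pixel above background + 3 units, and uses the median across columns —
  robust to the minority of columns occupied by protrusion fingers or
  stray noise. Protrusion components must touch the front (detached
  supra-threshold specks are noise) and reach ≥ 3 px beyond it.
- **Track linking** joins instances in consecutive frames with overlapping
  column ranges; one frame of absence ends the track (retraction is scored
  at first absence). Durations are `(last − first + 1) × Δt`, so a
  single-frame protrusion lasts one interval — this makes a 2.5-min mean
  representable as a mixture of 2- and 4-min tracks at 2-min sampling.
- **Censoring.** Tracks touching the first or last movie frame have unknown
  true lifetimes and are excluded from mean-duration summaries by default.
  The residual selection effect of excluding right-censored tracks is
  < 0.2 % of the mean for the default movie length (45 frames).
- **Enrichment onset** is the first frame where the 36-px leading-edge box
  mean reaches 1.2 × the whole-footprint mean. The factor is configurable;
  no numeric criterion is published, and 1.2 cleanly separates the rendered
  ridge (ratio ≈ 1.4) from pre-enrichment frames (ratio ≈ 1.0).

## Statistics

`tally` rounds percentages to the nearest integer, half away from zero;
exact values in (99, 100) and (0, 1) display as “>99” and “<1”. One-way
ANOVA and Tukey–Kramer q are computed from explicit sums of squares, with
p-values from `scipy.stats.f` and `scipy.stats.studentized_range` (vetted
CDFs, accuracy well beyond the 1e-6 contract); the test suite cross-checks
them against `scipy.stats.f_oneway`, `scipy.stats.tukey_hsd`, the F = t²
identity, and (for the balanced two-way decomposition) `statsmodels`
`anova_lm`. Zero within-group variance with distinct means reports F = ∞,
p = 0 with an explicit flag. The two-way ANOVA is balanced-only; its
Bonferroni post-test compares factor-A levels within each B level with
p·m capped at 1. ANOVA on per-replicate percentage lists follows the source
convention for phenotype tables; count-based exact tests are deliberately
not substituted. Fractionation percentages are computed over all 8 loaded
fractions jointly — the S fractions are sequential supernatants, so these
are percentages of loaded material, not a closed mass balance.

## What passing tests do and do not show

The generator reproduces the *statistical structure* the measurements rely
on — punctate peaks on a profile, a front-offset ridge, finger protrusions
with calibrated lifetimes, a fixed event schedule — not the appearance of
real embryos. Recovery tests therefore validate the measurement code
(thresholding, linking, timing arithmetic) and the generator's calibration,
but say nothing about segmentation robustness on real microscopy, where
ROIs are drawn by hand, background varies within a frame, and protrusions
are scored by eye. ROI definition from raw images is explicitly out of
scope (ROIs are inputs or generator outputs).

## Numerical choices and problem sizes

Profiles are sampled at 1-px steps by bilinear interpolation
(`scipy.ndimage.map_coordinates`, order 1). Stochastic recovery tests use
20 movies × 45 frames per preset (a few thousand pooled tracks), null
calibration uses 1000 Monte-Carlo replicates, and the peak-detector
equivalence check uses 1000 random profiles; all complete in seconds. All
randomness flows from `numpy.random.default_rng` seeds; identical spec+seed
reruns are bit-identical, including the pipeline's output digests.

## Known limitations

- Lateral-view rectangle geometry; no 3D/4D rendering, no dorsal
  intercalation, no cell–cell junction structure.
- Fronts, events and durations are frame-quantized; no sub-frame timing.
- The protrusion criterion is a geometric operationalization of what was
  originally manual scoring; absolute track counts in noisy real data will
  depend on the margin and minimum-extent settings.
- The two-way ANOVA accepts balanced designs only.
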