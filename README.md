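# epiactin

Quantitation of epidermal F-actin dynamics during *C. elegans* ventral
enclosure, for researchers analysing time-lapse fluorescence movies of
actin-reporter embryos (and anyone who wants a fully synthetic, ground-truthed
test bed for such measurements).

During ventral enclosure the epidermis migrates over the embryo surface:
two anterior **Leading Cells (LCs)** per side extend actin-rich protrusions
that guide the migration, and posterior **pocket cells** protrude later to
seal the ventral pocket. `epiactin` implements the standard measurements made
on such movies:

- **Leading-edge intensity** — the mean of a 36 × 36 px box anchored at the
  midpoint of a cell's leading edge, extending dorsally (≈ one third of the
  cell length).
- **Ventral:dorsal polarization** — intensity profiles sampled along a
  ventral→dorsal line through the cell; *peaks* are maximal contiguous
  regions at least 10 fluorescent units above background; counts pooled over
  a 20-frame (40 min) window give the polarization statistic
  *R = Σ ventral peaks / Σ dorsal peaks*.
- **Enrichment offset** — the distance (µm) from the protrusive front
  (ventral-most above-background sample on the axis) to the profile's
  intensity apex.
- **Protrusion lifetimes** — per frame, connected above-background
  components extending ≥ 3 px ventral of the cell front are protrusion
  instances; instances linked across consecutive frames form tracks with
  duration *(last − first + 1) × Δt*.
- **Event timing** — pocket-protrusion onset, leading-edge enrichment
  (box mean ≥ 1.2 × whole-cell mean), LC protrusion onset, and LC meeting
  (front crossing a configured meeting line), in minutes after first
  cleavage.
- **Phenotype statistics** — Gex-class tallies into integer percentages
  with total lethality, SEM, one-way ANOVA + Tukey HSD, balanced two-way
  ANOVA + Bonferroni post-tests.
- **Densitometry arithmetic** — loading-control normalization relative to
  wild type, RNAi depletion percentages, and sequential-fractionation
  (S1,P1..S4,P4) percentages.

Because no raw imaging data of this kind is publicly deposited, the package
ships a seeded synthetic movie generator (`epiactin.simulate`) whose genotype
presets encode the published event schedule and protrusion lifetimes
(wild type: pocket protrusions at 250 min, enrichment at 260 min, LC meeting
at 320 min, mean protrusion lifetime 2.5 min; gex-3: 9 min lifetimes, no
enrichment, no meeting; …) and which records a complete ground truth for
every structure it renders.

## Worked example

```bash
epiactin demo --outdir demo-out --seed 7
```

runs simulate → quantify → events → protrusions → stats on a wild-type-preset
movie and prints (abridged):

```json
{
 "background": 12.0,
 "enrichment_offset_um": {"LC-1": 1.95, "LC-2": 1.95},
 "events": {
  "t_pocket_protrusion": 250.0,
  "t_lc_enrichment": 260.0,
  "t_lc_protrusion": 262.0,
  "t_lc_meeting": 320.0
 },
 "mean_protrusion_duration_min": 2.465,
 "protrusion_duration_sem_min": 0.067,
 "start_frame": 10,
 "vd_ratio": {
  "LC-1": {"ventral": 45, "dorsal": 5, "ratio": 9.0},
  "LC-2": {"ventral": 50, "dorsal": 11, "ratio": 4.55}
 }
}
```

Reading the numbers: the four morphogenetic events are detected at exactly
the preset schedule (250/260/262/320 min after first cleavage); protrusions
turn over with a mean lifetime of ≈ 2.5 min; the F-actin apex sits 1.95 µm
(13 px at 0.15 µm/px) dorsal of the protrusive front; and ventral peaks
outnumber dorsal peaks in both Leading Cells over the 20-frame window
starting at enrichment onset (the window includes the leading-edge ridge,
which is itself a ventral peak, so the ratio exceeds the puncta-placement
odds of 3:1). The run directory contains `quantify.csv` (per-frame box means
and half counts), `protrusions.csv`, `events.json`, `summary.json` and a
`manifest.json` with SHA-256 digests — reruns with the same seed are
bit-identical.

Individual stages are available as `epiactin simulate | quantify | events |
protrusions | stats | biochem` (see `--help`), or as plain library calls.

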