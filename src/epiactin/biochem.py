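"""Densitometry arithmetic for western blots and subcellular fractionations.

Inputs are band-intensity tables (gel-image densitometry itself is out of
scope).  Three computations are provided: loading-control normalization
relative to a reference lane, RNAi depletion percentage, and the relative
percentage of total protein in each fraction of a sequential-centrifugation
series (S1, P1 .. S4, P4; spins 1K/10 min, 10K/10 min, 30K/20 min,
100K/90 min, each pellet resuspended to the volume of its partner
supernatant so equal loaded volumes are comparable).

Percentages are computed over all 8 loaded fractions jointly: the S
fractions are sequential supernatants, so these are percentages of loaded
material, not a closed mass balance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

FRACTION_NAMES = ("S1", "P1", "S2", "P2", "S3", "P3", "S4", "P4")
SPIN_SCHEME = {
    1: "1K rpm, 10 min",
    2: "10K rpm, 10 min",
    3: "30K rpm, 20 min",
    4: "100K rpm, 90 min",
}


@dataclass
class DensitometryRecord:
    """One lane: band of interest plus its loading control (tubulin/HSP90 role)."""

    label: str
    band_intensity: float
    control_intensity: float

    def __post_init__(self) -> None:
        if self.band_intensity < 0:
            raise ValueError(f"{self.label}: band intensity must be >= 0")
        if self.control_intensity <= 0:
            raise ValueError(f"{self.label}: loading control must be > 0")

    @property
    def normalized(self) -> float:
        return self.band_intensity / self.control_intensity


@dataclass
class FractionationSeries:
    """Band intensities of the 8 sequential-centrifugation fractions."""

    intensities: np.ndarray
    names: tuple = FRACTION_NAMES
    spin_scheme: dict = field(default_factory=lambda: dict(SPIN_SCHEME))

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.shape != (len(self.names),):
            raise ValueError(f"need {len(self.names)} fraction intensities")
        if np.any(self.intensities < 0):
            raise ValueError("fraction intensities must be >= 0")
        if not np.any(self.intensities > 0):
            raise ValueError("at least one fraction must be positive")


def normalize_relative(records: list, reference_label: str = "wild type") -> dict:
    """Loading-control-normalized band levels relative to a reference lane.

    r_i = (band_i / control_i) / (band_ref / control_ref); the reference lane
    maps to exactly 1.0.  Invariant under per-lane exposure scaling (band and
    control multiplied by the same constant).
    """
    by_label = {r.label: r for r in records}
    if reference_label not in by_label:
        raise ValueError(f"reference lane {reference_label!r} not present")
    ref = by_label[reference_label]
    if ref.band_intensity == 0:
        raise ValueError("reference band intensity is zero; cannot normalize")
    return {r.label: r.normalized / ref.normalized for r in records}


def depletion_percent(reference_level: float, treated_level: float) -> float:
    """Percent loss of a normalized level relative to the reference.

    100 * (1 - treated/reference).  A treated level above the reference would
    give a negative loss; it is clamped to 0 with a warning.
    """
    if reference_level <= 0:
        raise ValueError("reference level must be > 0")
    pct = 100.0 * (1.0 - treated_level / reference_level)
    if pct < 0:
        warnings.warn("treated level exceeds reference; depletion clamped to 0%")
        return 0.0
    return pct


def fraction_percentages(series: FractionationSeries, rounded: bool = False) -> dict:
    """Relative percentage of total loaded protein in each fraction.

    Exact percentages sum to 100 by construction and are invariant under
    global intensity scaling; with ``rounded`` they are displayed as
    integers (half away from zero), matching printed blot annotations.
    """
    total = series.intensities.sum()
    if total <= 0:
        raise ValueError("all-zero fractionation series")
    pct = 100.0 * series.intensities / total
    if rounded:
        return {
            name: int(np.floor(p + 0.5)) for name, p in zip(series.names, pct)
        }
    return {name: float(p) for name, p in zip(series.names, pct)}
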