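"""Chromosome sizing from bivariate flow-karyotype peaks.

Chromosomes stained with Hoechst 33258 (AT-preferring) and chromomycin A3
(GC-preferring) produce one peak per chromosome type in a bivariate
fluorescence plot.  Total DNA content is, to good approximation, proportional
to the distance of a peak from the origin along the "DNA-line" — the ray from
the origin through the peak of a designated anchor chromosome (human
chromosome 4 by convention).  Projecting every peak onto that line and
regressing known reference chromosome sizes on the projected distances gives
a linear size model (conversion x distance + offset) that converts target
peak distances into Mb.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .records import ChromosomeSpec


@dataclass
class FlowPeak:
    """One chromosome peak in (Hoechst, chromomycin) intensity space."""

    chromosome: str
    species: str  # "target" or "reference"
    x: float
    y: float

    def __post_init__(self) -> None:
        if self.x < 0 or self.y < 0:
            raise ValidationError(f"peak {self.chromosome}: intensities must be >= 0")
        if self.x == 0 and self.y == 0:
            raise ValidationError(f"peak {self.chromosome}: both intensities zero")


@dataclass
class SizeCalibration:
    """Linear model size_mb = conversion x distance + offset along the DNA-line."""

    line_unit: tuple[float, float]
    conversion: float
    offset: float
    residuals_mb: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.conversion <= 0:
            raise ValidationError(f"conversion must be > 0, got {self.conversion}")


def project_onto_dna_line(peaks: list[FlowPeak], anchor: FlowPeak) -> dict[str, float]:
    """Scalar projection of each peak onto the ray through ``anchor``.

    The anchor's own distance equals its Euclidean norm.  Projection is
    linear in the peak coordinates.
    """
    norm = float(np.hypot(anchor.x, anchor.y))
    if norm == 0:
        raise ValidationError("anchor peak at origin: DNA-line undefined")
    ux, uy = anchor.x / norm, anchor.y / norm
    return {p.chromosome: p.x * ux + p.y * uy for p in peaks}


def calibrate(human_distances: dict[str, float], human_sizes_mb: dict[str, float]) -> SizeCalibration:
    """Least-squares fit of reference sizes on projected distances.

    Uses every chromosome present in both inputs; needs at least two and
    non-degenerate distances.
    """
    common = sorted(set(human_distances) & set(human_sizes_mb))
    if len(common) < 2:
        raise ValidationError(f"calibration needs >= 2 reference chromosomes, got {len(common)}")
    d = np.array([human_distances[c] for c in common], dtype=float)
    s = np.array([human_sizes_mb[c] for c in common], dtype=float)
    if np.ptp(d) == 0:
        raise ValidationError("all reference distances identical: singular fit")
    conversion, offset = np.polyfit(d, s, 1)
    fitted = conversion * d + offset
    residuals = {c: float(s[i] - fitted[i]) for i, c in enumerate(common)}
    return SizeCalibration(line_unit=(np.nan, np.nan), conversion=float(conversion),
                           offset=float(offset), residuals_mb=residuals)


def estimate_sizes(target_distances: dict[str, float], cal: SizeCalibration,
                   size_cm: dict[str, float] | None = None) -> list[ChromosomeSpec]:
    """Convert target peak distances to Mb, rounded to integer Mb.

    ``size_cm`` optionally supplies full-coverage linkage lengths; a
    placeholder of 1 cM/Mb is used when absent so the record validates.
    """
    specs = []
    for chrom in target_distances:
        mb = cal.conversion * target_distances[chrom] + cal.offset
        if mb <= 0:
            raise ValidationError(
                f"{chrom}: estimated size {mb:.1f} Mb <= 0; calibration out of range"
            )
        mb = float(round(mb))
        cm = size_cm.get(chrom, mb) if size_cm else mb
        specs.append(ChromosomeSpec(name=chrom, size_mb=mb, size_cm=cm))
    return specs


def genome_size(sizes: list[ChromosomeSpec]) -> tuple[float, float]:
    """Total genome size as (Mb, cM) sums over chromosomes."""
    names = [s.name for s in sizes]
    if len(set(names)) != len(names):
        raise ValidationError("duplicate chromosome labels in genome size sum")
    return (
        float(sum(s.size_mb for s in sizes)),
        float(round(sum(s.size_cm for s in sizes), 2)),
    )
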