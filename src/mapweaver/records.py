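"""Domain records shared by every stage of map construction.

Coordinate conventions
----------------------
Positions along a target chromosome are measured in kb from the p-telomere,
with ``ptr`` at 0.  Cytogenetic bands are half-open kb intervals
``[start, end)``.  Reference-genome coordinates (``ref_bp``) are base pairs.
Genetic positions are centimorgans with ``ptr`` at 0 and ``qtr`` at the
chromosome's full-coverage linkage length.

The three landmark names ``ptr`` (p-telomere), ``cen`` (centromere) and
``qtr`` (q-telomere) are reserved locus names recognised throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ValidationError

LANDMARKS = ("ptr", "cen", "qtr")


def is_landmark(name: str) -> bool:
    return name in LANDMARKS


@dataclass
class ChromosomeSpec:
    """Physical (Mb) and full-coverage linkage (cM) size of one chromosome."""

    name: str
    size_mb: float
    size_cm: float

    def __post_init__(self) -> None:
        if self.size_mb <= 0:
            raise ValidationError(f"{self.name}: size_mb must be > 0, got {self.size_mb}")
        if self.size_cm <= 0:
            raise ValidationError(f"{self.name}: size_cm must be > 0, got {self.size_cm}")

    @property
    def size_kb(self) -> float:
        return self.size_mb * 1000.0


@dataclass
class ArmSpec:
    """One chromosome arm with physical and sex-specific genetic lengths.

    Sex-pooled data duplicates the pooled cM length into both sex columns.
    """

    arm: str  # "p" or "q"
    size_mb: float
    size_cm_male: float
    size_cm_female: float
    chromosome: str = ""

    def __post_init__(self) -> None:
        if self.arm not in ("p", "q"):
            raise ValidationError(f"arm must be 'p' or 'q', got {self.arm!r}")
        if self.size_mb < 0 or self.size_cm_male < 0 or self.size_cm_female < 0:
            raise ValidationError(f"arm {self.arm}: sizes must be non-negative")


@dataclass
class BandSpec:
    """A cytogenetic band as an interval in Mb from the p-telomere."""

    band_id: str
    size_mb: float
    start_mb: float
    end_mb: float

    def __post_init__(self) -> None:
        if abs((self.end_mb - self.start_mb) - self.size_mb) > 1e-3:
            raise ValidationError(
                f"band {self.band_id}: end - start = "
                f"{self.end_mb - self.start_mb:.4f} != size {self.size_mb:.4f}"
            )
        if self.size_mb <= 0:
            raise ValidationError(f"band {self.band_id}: size must be positive")

    @property
    def start_kb(self) -> float:
        return self.start_mb * 1000.0

    @property
    def end_kb(self) -> float:
        return self.end_mb * 1000.0

    def contains_kb(self, kb: float) -> bool:
        """Half-open containment [start, end)."""
        return self.start_kb <= kb < self.end_kb


@dataclass
class FishAssignment:
    """A locus FISH-mapped to one band or a contiguous band range.

    ``band_start`` is the band on the p-telomere side of the signal,
    ``band_end`` the band on the q-telomere side; equal for single-band
    assignments.
    """

    locus: str
    band_start: str
    band_end: str


@dataclass
class LinkageEntry:
    """A locus on the linkage map (sex-pooled input duplicates the value)."""

    locus: str
    cm_male: float
    cm_female: float

    @property
    def cm(self) -> float:
        """Sex-averaged position (equals either column for pooled data)."""
        return 0.5 * (self.cm_male + self.cm_female)


@dataclass
class LinkageCoverage:
    """Coverage of a chromosome by its source linkage map.

    ``m_percent`` is the size of the uncovered p-telomeric end expressed as a
    percentage of the covered length; the anchoring offset in cM is
    ``m_percent/100 x map_length_cm``.
    """

    chromosome: str
    map_length_cm: float
    m_percent: float

    def __post_init__(self) -> None:
        if self.m_percent < 0:
            raise ValidationError(f"{self.chromosome}: m_percent must be >= 0")
        if self.map_length_cm <= 0:
            raise ValidationError(f"{self.chromosome}: map_length_cm must be > 0")

    @property
    def offset_cm(self) -> float:
        return self.m_percent / 100.0 * self.map_length_cm


@dataclass
class BreakpointEntry:
    """An evolutionary breakpoint position in kb from the p-telomere."""

    id: str
    kb: float

    def __post_init__(self) -> None:
        if self.kb < 0:
            raise ValidationError(f"breakpoint {self.id}: kb must be >= 0")


@dataclass
class OrthologueRecord:
    """A locus with the position of its orthologue in a reference assembly."""

    locus: str
    ref_bp: float
    ref_chromosome: str

    def __post_init__(self) -> None:
        if self.ref_bp < 0:
            raise ValidationError(f"{self.locus}: ref_bp must be >= 0")


@dataclass
class MapEntry:
    """One row of an integrated or virtual map.

    ``confidence`` is 2 for loci mapped in the target species, 1 for loci
    interpolated within an oriented conserved block, 0 within an unoriented
    block, and None (printed NA) for landmarks.
    """

    locus: str
    kb: float
    cm: float
    band: str
    confidence: int | None = None
    source: str = "interpolated"  # FISH | linkage | breakpoint | interpolated | landmark
    external_id: str = ""


@dataclass
class ChromosomeFrame:
    """Per-chromosome geometry assembled before integration."""

    spec: ChromosomeSpec
    arms: list[ArmSpec]
    bands: list[BandSpec]
    centromere_kb: float
    breakpoints: list[BreakpointEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.arms:
            p = next((a for a in self.arms if a.arm == "p"), None)
            if p is not None and abs(self.centromere_kb - p.size_mb * 1000.0) > 1.0:
                raise ValidationError(
                    f"{self.spec.name}: centromere at {self.centromere_kb} kb "
                    f"disagrees with p-arm size {p.size_mb} Mb"
                )
        if self.bands:
            validate_band_tiling(self.bands, self.spec.size_mb)

    @property
    def p_arm(self) -> ArmSpec:
        return next(a for a in self.arms if a.arm == "p")

    @property
    def q_arm(self) -> ArmSpec:
        return next(a for a in self.arms if a.arm == "q")

    def band_of(self, kb: float) -> str:
        """Band containing ``kb`` (half-open; the q-telomere closes the last band)."""
        for b in self.bands:
            if b.contains_kb(kb):
                return b.band_id
        if self.bands and abs(kb - self.bands[-1].end_kb) <= 1e-6:
            return self.bands[-1].band_id
        raise ValidationError(f"{self.spec.name}: kb {kb} outside band tiling")


def validate_band_tiling(bands: list[BandSpec], size_mb: float, tol_mb: float = 1e-3) -> None:
    """Bands must be contiguous, non-overlapping and tile [0, size_mb]."""
    if not bands:
        raise ValidationError("empty band list")
    if abs(bands[0].start_mb) > tol_mb:
        raise ValidationError(f"first band starts at {bands[0].start_mb}, expected 0")
    for prev, nxt in zip(bands, bands[1:]):
        if abs(nxt.start_mb - prev.end_mb) > tol_mb:
            raise ValidationError(
                f"band gap/overlap between {prev.band_id} (end {prev.end_mb}) "
                f"and {nxt.band_id} (start {nxt.start_mb})"
            )
    if abs(bands[-1].end_mb - size_mb) > tol_mb:
        raise ValidationError(
            f"last band ends at {bands[-1].end_mb}, expected chromosome size {size_mb}"
        )


def validate_map_monotone(entries: list[MapEntry], tol_cm: float = 1e-9) -> None:
    """Entries sorted by kb must be non-decreasing in cM."""
    ordered = sorted(entries, key=lambda e: e.kb)
    for prev, nxt in zip(ordered, ordered[1:]):
        if nxt.cm < prev.cm - tol_cm:
            raise ValidationError(
                f"cM decreases from {prev.locus} ({prev.cm}) to {nxt.locus} ({nxt.cm}) "
                "when sorted by kb"
            )
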