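"""Centromere placement, arm sizing and cytogenetic band interpolation.

The centromere is placed at the breakpoint between the two conserved blocks
that FISH evidence puts on opposite arms; when it falls inside one block it
is placed at the reference midpoint of the two flanking markers, rescaled
onto the block's target extent.  Arm cM lengths start proportional to arm Mb
lengths and are minimally shifted so the centromere's cM lies strictly
between the flanking p-arm and q-arm markers.  Band boundaries come from the
standard idiogram's proportional positions, linearly interpolated within
each arm's kb length.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import PlacementError, ValidationError
from .records import ArmSpec, BandSpec, ChromosomeSpec
from .synteny import Marker, SyntenyBlock

EPS_CM = 0.01  # margin for "strictly between" adjustments


@dataclass
class IdiogramBand:
    """A band's proportional interval within its arm, measured from the
    arm's outer end (p: from p-telomere; q: from centromere)."""

    band_id: str
    start_fraction: float
    end_fraction: float

    def __post_init__(self) -> None:
        if not (0 <= self.start_fraction < self.end_fraction <= 1):
            raise ValidationError(
                f"band {self.band_id}: fractions must satisfy 0 <= start < end <= 1"
            )


def place_centromere(blocks: list[SyntenyBlock], p_arm_loci: set[str],
                     q_arm_loci: set[str]) -> float:
    """Centromere kb = the breakpoint between the last block containing
    p-arm FISH markers and the first containing q-arm markers.

    Raises PlacementError when the p/q transition falls inside a block
    (use place_centromere_within_block) or cannot be found.
    """
    last_p = first_q = None
    for i, b in enumerate(blocks):
        names = {m.locus for m in b.members}
        if names & p_arm_loci:
            last_p = i
        if names & q_arm_loci and first_q is None:
            first_q = i
    if last_p is None or first_q is None:
        raise PlacementError("no FISH evidence for one of the arms")
    if last_p == first_q:
        raise PlacementError(
            f"p/q transition lies within block {blocks[last_p].block_id}; "
            "place within the block using its flanking markers"
        )
    if last_p > first_q:
        raise PlacementError("FISH arm assignments are interleaved across blocks")
    if blocks[last_p].target_end_kb is None:
        raise PlacementError("blocks must be scaled to target before centromere placement")
    return float(blocks[last_p].target_end_kb)


def place_centromere_within_block(block: SyntenyBlock, flank_left: Marker,
                                  flank_right: Marker) -> float:
    """Reference midpoint of the two flanking markers, affinely rescaled
    (orientation-aware) onto the block's target kb extent."""
    names = {m.locus for m in block.members}
    if flank_left.locus not in names or flank_right.locus not in names:
        raise PlacementError("flanking markers are not members of the block")
    if block.target_start_kb is None or block.target_end_kb is None:
        raise PlacementError("block has no target extent")
    bp_left = flank_left.coord(block.ref_genome)[1]
    bp_right = flank_right.coord(block.ref_genome)[1]
    mid_bp = 0.5 * (bp_left + bp_right)
    return ref_to_target_kb(block, mid_bp)


def ref_to_target_kb(block: SyntenyBlock, ref_bp: float) -> float:
    """Affine map of a reference position onto the block's target extent,
    reversed for reverse-orientation blocks."""
    span_ref = block.ref_end_bp - block.ref_start_bp
    if span_ref <= 0:
        raise ValidationError(f"block {block.block_id}: degenerate reference extent")
    frac = (ref_bp - block.ref_start_bp) / span_ref
    if block.orientation == "reverse":
        frac = 1.0 - frac
    return block.target_start_kb + frac * (block.target_end_kb - block.target_start_kb)


def arm_sizes(chromosome: ChromosomeSpec, centromere_kb: float,
              p_flank_cm: float | None = None, q_flank_cm: float | None = None,
              fallback_ratio: tuple[float, float] | None = None) -> list[ArmSpec]:
    """Split the chromosome into p/q arms at the centromere.

    cM arm lengths are first proportional to Mb lengths, then the boundary is
    minimally shifted so the centromere cM lies strictly (margin 0.01 cM)
    between the flanking markers' cM positions.  ``fallback_ratio`` (p, q)
    replaces the centromere-based Mb split when no block evidence exists.
    """
    size_kb = chromosome.size_kb
    if fallback_ratio is not None:
        p_frac = fallback_ratio[0] / (fallback_ratio[0] + fallback_ratio[1])
        centromere_kb = p_frac * size_kb
    if not (0 < centromere_kb < size_kb):
        raise ValidationError(
            f"{chromosome.name}: centromere {centromere_kb} kb outside (0, {size_kb})"
        )
    p_mb = centromere_kb / 1000.0
    q_mb = chromosome.size_mb - p_mb
    p_cm = chromosome.size_cm * p_mb / chromosome.size_mb
    if p_flank_cm is not None and q_flank_cm is not None:
        if p_flank_cm >= q_flank_cm:
            raise ValidationError(
                f"{chromosome.name}: flanking cM inverted ({p_flank_cm} >= {q_flank_cm})"
            )
        if p_cm <= p_flank_cm:
            p_cm = min(p_flank_cm + EPS_CM, 0.5 * (p_flank_cm + q_flank_cm))
        elif p_cm >= q_flank_cm:
            p_cm = max(q_flank_cm - EPS_CM, 0.5 * (p_flank_cm + q_flank_cm))
    q_cm = chromosome.size_cm - p_cm
    return [
        ArmSpec(arm="p", size_mb=p_mb, size_cm_male=p_cm, size_cm_female=p_cm,
                chromosome=chromosome.name),
        ArmSpec(arm="q", size_mb=q_mb, size_cm_male=q_cm, size_cm_female=q_cm,
                chromosome=chromosome.name),
    ]


def interpolate_bands(p_idiogram: list[IdiogramBand], q_idiogram: list[IdiogramBand],
                      arms: list[ArmSpec]) -> list[BandSpec]:
    """Translate proportional idiogram band borders into Mb intervals.

    p-arm fractions run from the p-telomere toward the centromere, q-arm
    fractions from the centromere toward the q-telomere; the output tiles
    [0, chromosome size] in file order ptr -> qtr.
    """
    p_arm = next(a for a in arms if a.arm == "p")
    q_arm = next(a for a in arms if a.arm == "q")
    _check_tiling(p_idiogram, "p")
    _check_tiling(q_idiogram, "q")
    bands: list[BandSpec] = []
    for ib in p_idiogram:
        start = ib.start_fraction * p_arm.size_mb
        end = ib.end_fraction * p_arm.size_mb
        bands.append(BandSpec(ib.band_id, round(end - start, 6), round(start, 6), round(end, 6)))
    for ib in q_idiogram:
        start = p_arm.size_mb + ib.start_fraction * q_arm.size_mb
        end = p_arm.size_mb + ib.end_fraction * q_arm.size_mb
        bands.append(BandSpec(ib.band_id, round(end - start, 6), round(start, 6), round(end, 6)))
    return bands


def _check_tiling(idiogram: list[IdiogramBand], arm: str) -> None:
    if not idiogram:
        raise ValidationError(f"{arm} arm: empty idiogram")
    if abs(idiogram[0].start_fraction) > 1e-9 or abs(idiogram[-1].end_fraction - 1) > 1e-9:
        raise ValidationError(f"{arm} arm: idiogram does not span [0, 1]")
    for a, b in zip(idiogram, idiogram[1:]):
        if abs(b.start_fraction - a.end_fraction) > 1e-9:
            raise ValidationError(
                f"{arm} arm: idiogram gap between {a.band_id} and {b.band_id}"
            )
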