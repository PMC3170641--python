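"""The map-integration engine.

Combines, for one chromosome, FISH band assignments, a rescaled linkage map,
evolutionary breakpoints and comparative orthologue positions into a single
monotone map in which every locus has a kb, a cM and a band location.

Placement logic
---------------
* FISH-mapped loci are seeded at the midpoint of their assigned band
  interval, then fine-tuned by the orthologue positions of their conserved
  block (affine transform of reference bp onto the block's target extent),
  clamped back into the assigned band interval.
* Loci on the linkage map keep their (offset-anchored) cM; loci mapped by
  linkage only receive a kb by cM-proportional placement between the nearest
  kb-anchored neighbours.
* Breakpoints and FISH-only loci receive cM by piecewise-linear
  interpolation between cM-anchored neighbours (ptr at 0, qtr at the full
  linkage length).
* Where FISH order and linkage order disagree, the physical (FISH) order
  wins: the conflicting linkage cM is discarded for anchoring, the locus is
  reported, and its cM is interpolated instead.

Band definitions are then iteratively curated: any FISH locus whose
integrated kb falls outside its assigned band gets the nearer band boundary
moved the minimal distance to include it, bands are re-tiled, and
integration repeats until no discrepancy remains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import IntegrationError, ValidationError
from .records import (
    BandSpec,
    ChromosomeFrame,
    FishAssignment,
    LinkageCoverage,
    LinkageEntry,
    MapEntry,
    is_landmark,
)
from .geometry import ref_to_target_kb
from .synteny import SyntenyBlock

_SOURCE_PRIORITY = {"FISH": 0, "linkage": 1, "breakpoint": 2, "landmark": 3,
                    "interpolated": 4}


@dataclass
class IntegrationState:
    frame: ChromosomeFrame
    entries: list[MapEntry] = field(default_factory=list)
    curation_round: int = 0
    band_edits: list[tuple[str, float, float]] = field(default_factory=list)
    conflicts: list[str] = field(default_factory=list)


def rescale_linkage(entries: list[LinkageEntry], coverage: LinkageCoverage,
                    target_cm: float) -> list[LinkageEntry]:
    """Anchor a partial-coverage linkage map to the full chromosome.

    Adds ``offset_cm = m%/100 x map length`` to every marker (shifting the
    covered interval away from the p-telomere) and appends ptr at 0 and qtr
    at ``target_cm``.
    """
    offset = coverage.offset_cm
    out: list[LinkageEntry] = []
    for e in entries:
        if is_landmark(e.locus):
            continue  # landmarks are re-anchored below
        male, female = e.cm_male + offset, e.cm_female + offset
        if max(male, female) > target_cm + 1e-6:
            raise ValidationError(
                f"{e.locus}: rescaled cM {max(male, female):.2f} exceeds "
                f"chromosome length {target_cm:.2f}; coverage inconsistent"
            )
        out.append(LinkageEntry(e.locus, male, female))
    out.append(LinkageEntry("ptr", 0.0, 0.0))
    out.append(LinkageEntry("qtr", target_cm, target_cm))
    return out


def seed_fish_positions(fish: list[FishAssignment], bands: list[BandSpec]
                        ) -> dict[str, float]:
    """Provisional kb per FISH locus: midpoint of its band interval union."""
    positions = {}
    for f in fish:
        lo, hi = band_union_kb(f, bands)
        positions[f.locus] = 0.5 * (lo + hi)
    return positions


def band_union_kb(f: FishAssignment, bands: list[BandSpec]) -> tuple[float, float]:
    """kb interval spanned by a FISH assignment's band range."""
    by_id = {b.band_id: b for b in bands}
    try:
        start, end = by_id[f.band_start], by_id[f.band_end]
    except KeyError as exc:
        raise ValidationError(f"{f.locus}: unknown band id {exc}") from None
    if start.start_kb > end.start_kb:
        raise ValidationError(
            f"{f.locus}: band range {f.band_start}..{f.band_end} is inverted"
        )
    return start.start_kb, end.end_kb


def refine_with_orthologues(provisional: dict[str, float],
                            blocks: list[SyntenyBlock],
                            band_unions: dict[str, tuple[float, float]] | None = None,
                            ) -> dict[str, float]:
    """Fine-tune FISH loci within their conserved block.

    Each locus that is a member of a scaled block is placed by the
    orientation-aware affine transform of its reference position onto the
    block's target extent, then clamped to its FISH band interval.  Loci in
    no block keep their provisional position.
    """
    refined = dict(provisional)
    for block in blocks:
        if block.target_start_kb is None:
            raise ValidationError(f"block {block.block_id} has no target extent")
        for m in block.members:
            if m.locus not in refined:
                continue
            kb = ref_to_target_kb(block, m.coord(block.ref_genome)[1])
            if band_unions and m.locus in band_unions:
                lo, hi = band_unions[m.locus]
                kb = min(max(kb, lo), max(lo, hi - 1.0))
            refined[m.locus] = kb
    return refined


def interpolate_cm(kb: float, anchors: list[tuple[float, float]]) -> float:
    """Piecewise-linear cM at ``kb`` between flanking (kb, cM) anchors.

    Anchors must include the telomeres, be strictly increasing in kb and
    non-decreasing in cM; the result is exact at anchors.
    """
    if not anchors:
        raise ValidationError("no anchors for cM interpolation")
    kbs = [a[0] for a in anchors]
    cms = [a[1] for a in anchors]
    if any(b <= a for a, b in zip(kbs, kbs[1:])):
        raise ValidationError("anchor kb values must be strictly increasing")
    if any(b < a - 1e-9 for a, b in zip(cms, cms[1:])):
        raise ValidationError("anchor cM values must be non-decreasing")
    if kb < kbs[0] - 1e-9 or kb > kbs[-1] + 1e-9:
        raise ValidationError(f"kb {kb} outside anchored range [{kbs[0]}, {kbs[-1]}]")
    return float(np.interp(kb, kbs, cms))


def integrate_chromosome(
    frame: ChromosomeFrame,
    fish: list[FishAssignment],
    linkage: list[LinkageEntry] | None = None,
    coverage: LinkageCoverage | None = None,
    blocks: list[SyntenyBlock] | None = None,
    clamp_to_band: bool = True,
) -> tuple[list[MapEntry], list[str]]:
    """Build the integrated map of one chromosome.

    Returns the monotone entry list (landmarks included) and the conflict
    report (loci whose linkage order contradicted the FISH order; the FISH
    order was kept and their cM interpolated).  ``clamp_to_band=False``
    leaves comparative placements free of the band intervals — the state in
    which band curation measures its discrepancies.
    """
    spec = frame.spec
    size_kb, size_cm = spec.size_kb, spec.size_cm
    cen_cm = frame.p_arm.size_cm_male

    unions = {f.locus: band_union_kb(f, frame.bands) for f in fish}
    provisional = seed_fish_positions(fish, frame.bands)
    kb_pos = (refine_with_orthologues(provisional, blocks,
                                      unions if clamp_to_band else None)
              if blocks else provisional)
    # clamp placements into [0, size); the q-telomere itself closes the map
    kb_pos = {loc: min(max(kb, 0.0), size_kb - 1.0) for loc, kb in kb_pos.items()}

    linkage_cm: dict[str, float] = {}
    if linkage:
        anchored = (rescale_linkage(linkage, coverage, size_cm) if coverage
                    else linkage)
        for e in anchored:
            if not is_landmark(e.locus):
                if not (-1e-6 <= e.cm <= size_cm + 1e-6):
                    raise ValidationError(
                        f"{e.locus}: cM {e.cm:.2f} outside [0, {size_cm:.2f}]"
                    )
                linkage_cm[e.locus] = min(max(e.cm, 0.0), size_cm)

    landmarks = [(0.0, 0.0, "ptr"), (frame.centromere_kb, cen_cm, "cen"),
                 (size_kb, size_cm, "qtr")]

    # candidate dual anchors: FISH-placed loci that also have a linkage cM
    dual = sorted(
        ((kb_pos[loc], linkage_cm[loc], loc) for loc in kb_pos if loc in linkage_cm),
        key=lambda t: t[0],
    )
    kept, conflicts = _consistent_anchor_subset(dual, landmarks)
    anchors = _merge_anchors(landmarks, kept)

    entries: list[MapEntry] = []
    for kb, cm, name in landmarks:
        band = "cen" if name == "cen" else frame.band_of(kb)
        if name == "qtr":
            band = "qtr"
        entries.append(MapEntry(name, kb, cm, band, None, "landmark"))

    kept_loci = {t[2] for t in kept}
    for locus, kb in kb_pos.items():
        cm = linkage_cm[locus] if locus in kept_loci else interpolate_cm(kb, anchors)
        band = _fish_band(frame, unions[locus], kb)
        entries.append(MapEntry(locus, kb, cm, band, 2, "FISH"))

    # linkage-only loci: kb by cM-proportional placement between kb anchors
    inv_anchors = _invertible(anchors)
    for locus, cm in linkage_cm.items():
        if locus in kb_pos:
            continue
        kb = float(np.interp(cm, [a[1] for a in inv_anchors], [a[0] for a in inv_anchors]))
        entries.append(MapEntry(locus, kb, cm, frame.band_of(kb), 2, "linkage"))

    for bp in frame.breakpoints:
        if is_landmark(bp.id):
            continue
        cm = interpolate_cm(bp.kb, anchors)
        entries.append(MapEntry(bp.id, bp.kb, cm, frame.band_of(bp.kb), None, "breakpoint"))

    def _rank(e: MapEntry) -> int:
        # the telomeres bracket everything at their kb; otherwise FISH
        # placements precede linkage, breakpoints, then landmarks
        if e.locus == "ptr":
            return -1
        if e.locus == "qtr":
            return 9
        return _SOURCE_PRIORITY.get(e.source, 8)

    entries.sort(key=lambda e: (e.kb, _rank(e), e.cm, e.locus))
    _assert_monotone(entries)
    return entries, conflicts


def _fish_band(frame: ChromosomeFrame, union: tuple[float, float], kb: float) -> str:
    """Band for a FISH-mapped locus: the assigned band containing kb (closed
    at the union's q end, so boundary loci keep their FISH band), else the
    tiling band (a discrepancy for curation to fix)."""
    lo, hi = union
    if lo <= kb <= hi:
        for b in frame.bands:
            if b.start_kb >= lo - 1e-9 and b.end_kb <= hi + 1e-9:
                if b.contains_kb(kb) or abs(kb - b.end_kb) < 1e-9 and b.end_kb >= hi - 1e-9:
                    return b.band_id
    return frame.band_of(kb)


def _consistent_anchor_subset(dual, landmarks):
    """Largest subset of dual-mapped loci whose cM is non-decreasing in kb
    order and consistent with the landmark anchors (longest non-decreasing
    subsequence); the rest are order conflicts."""
    filtered = []
    conflicts = []
    for kb, cm, loc in dual:
        ok = True
        for lkb, lcm, _ in landmarks:
            if (kb <= lkb and cm > lcm + 1e-9) or (kb >= lkb and cm < lcm - 1e-9):
                ok = False
        (filtered if ok else conflicts).append((kb, cm, loc))
    n = len(filtered)
    if n == 0:
        return [], [c[2] for c in conflicts]
    best_len = [1] * n
    prev = [-1] * n
    for i in range(n):
        for j in range(i):
            # strictly increasing kb: at most one cM anchor per position
            if (filtered[j][1] <= filtered[i][1] + 1e-12
                    and filtered[j][0] < filtered[i][0] - 1e-9
                    and best_len[j] + 1 > best_len[i]):
                best_len[i] = best_len[j] + 1
                prev[i] = j
    i = int(np.argmax(best_len))
    keep_idx = set()
    while i != -1:
        keep_idx.add(i)
        i = prev[i]
    kept = [filtered[i] for i in range(n) if i in keep_idx]
    conflicts += [filtered[i] for i in range(n) if i not in keep_idx]
    return kept, sorted(c[2] for c in conflicts)


def _merge_anchors(landmarks, kept) -> list[tuple[float, float]]:
    pts = sorted({(kb, cm) for kb, cm, _ in list(landmarks) + list(kept)})
    merged: list[tuple[float, float]] = []
    for kb, cm in pts:
        if merged and abs(kb - merged[-1][0]) < 1e-9:
            continue  # co-located anchors: keep the first (equal cm expected)
        merged.append((kb, cm))
    return merged


def _invertible(anchors) -> list[tuple[float, float]]:
    """Anchors thinned to strictly increasing cM for cM -> kb inversion."""
    out = [anchors[0]]
    for kb, cm in anchors[1:]:
        if cm > out[-1][1] + 1e-9:
            out.append((kb, cm))
        else:
            out[-1] = (kb, out[-1][1])
    return out


def _assert_monotone(entries: list[MapEntry]) -> None:
    for a, b in zip(entries, entries[1:]):
        if b.cm < a.cm - 1e-6:
            raise IntegrationError(
                f"integrated map not monotone: {a.locus} ({a.cm:.3f} cM) before "
                f"{b.locus} ({b.cm:.3f} cM)"
            )


def curate_bands(
    frame: ChromosomeFrame,
    fish: list[FishAssignment],
    linkage: list[LinkageEntry] | None = None,
    coverage: LinkageCoverage | None = None,
    blocks: list[SyntenyBlock] | None = None,
    max_rounds: int = 20,
) -> IntegrationState:
    """Iterate integration and minimal band-boundary extension to convergence.

    Each round integrates the chromosome, finds FISH loci lying outside
    their assigned band interval, moves the nearer boundary of the assigned
    band just far enough to include them (re-tiling the neighbours), and
    repeats.  The discrepancy count must strictly decrease every round;
    convergence means zero discrepancies.
    """
    state = IntegrationState(frame=frame)
    prev_count = None
    for round_no in range(max_rounds + 1):
        entries, conflicts = integrate_chromosome(frame, fish, linkage, coverage, blocks,
                                                  clamp_to_band=False)
        state.entries, state.conflicts, state.curation_round = entries, conflicts, round_no
        kb_of = {e.locus: e.kb for e in entries}
        discrepancies = []
        for f in fish:
            lo, hi = band_union_kb(f, frame.bands)
            kb = kb_of[f.locus]
            # boundaries count as inside (FISH loci keep their band at a
            # shared boundary), with the 1 kb epsilon of the coordinate grid
            if kb < lo - 1.0 or kb > hi + 1.0:
                discrepancies.append((f, kb, lo, hi))
        if not discrepancies:
            return state
        count = len(discrepancies)
        if prev_count is not None and count >= prev_count:
            raise IntegrationError(
                f"band curation stalled at round {round_no}: {count} discrepancies "
                f"({[d[0].locus for d in discrepancies]})"
            )
        prev_count = count
        for f, kb, lo, hi in discrepancies:
            _extend_band(frame, state, f, kb, lo, hi)
    raise IntegrationError(
        f"band curation did not converge within {max_rounds} rounds; "
        f"remaining: {[d[0].locus for d in discrepancies]}"
    )


def _extend_band(frame: ChromosomeFrame, state: IntegrationState,
                 f: FishAssignment, kb: float, lo: float, hi: float) -> None:
    """Move the nearer boundary of the assigned band minimally to cover kb,
    re-tiling the adjacent band (which must keep at least 1 kb)."""
    bands = frame.bands
    ids = [b.band_id for b in bands]
    if kb < lo:
        i = ids.index(f.band_start)
        new_start = max(kb, bands[i - 1].start_kb + 1.0 if i > 0 else 0.0) / 1000.0
        old = bands[i].start_mb
        bands[i] = BandSpec(bands[i].band_id, round(bands[i].end_mb - new_start, 9),
                            round(new_start, 9), bands[i].end_mb)
        if i > 0:
            p = bands[i - 1]
            bands[i - 1] = BandSpec(p.band_id, round(new_start - p.start_mb, 9),
                                    p.start_mb, round(new_start, 9))
        state.band_edits.append((f.band_start, old, new_start))
    else:
        i = ids.index(f.band_end)
        limit = bands[i + 1].end_kb - 1.0 if i + 1 < len(bands) else frame.spec.size_kb
        new_end = min(kb + 1.0, limit) / 1000.0
        old = bands[i].end_mb
        bands[i] = BandSpec(bands[i].band_id, round(new_end - bands[i].start_mb, 9),
                            bands[i].start_mb, round(new_end, 9))
        if i + 1 < len(bands):
            nx = bands[i + 1]
            bands[i + 1] = BandSpec(nx.band_id, round(nx.end_mb - new_end, 9),
                                    round(new_end, 9), nx.end_mb)
        state.band_edits.append((f.band_end, old, new_end))
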