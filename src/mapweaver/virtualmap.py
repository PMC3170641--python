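"""Virtual genome map construction and scaffold anchoring.

All reference-genome genes falling inside each conserved block's reference
extent are interpolated into the integrated map, inheriting a kb (affine,
orientation-aware, between the nearest mapped anchors), a cM (piecewise
linear) and a band.  Confidence levels: 2 = mapped in the target species
(the immutable integrated "backbone"), 1 = interpolated within a block
whose orientation is known, 0 = interpolated within an unoriented block.
Sequence scaffolds sharing genes with the virtual map are then anchored to
chromosome spans.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ValidationError
from .records import ChromosomeFrame, MapEntry, OrthologueRecord, is_landmark
from .integrate import interpolate_cm
from .synteny import SyntenyBlock


@dataclass
class ScaffoldAnchor:
    scaffold_id: str
    chromosome: str
    start_kb: float
    end_kb: float
    orientation: str  # forward | reverse | unknown
    n_genes_in_map: int


def build_orthologue_files(
    blocks: list[SyntenyBlock],
    annotation: dict[str, list[OrthologueRecord]],
    orphans: set[str] | None = None,
    preference: tuple[str, ...] = ("MDO", "HSA"),
) -> tuple[dict[str, list[OrthologueRecord]], list[str]]:
    """Per-block orthologue file: every annotation gene within the block's
    reference extent, orphans excluded.

    ``annotation`` maps reference-genome label to its gene records.  A gene
    claimed by several blocks is kept once — in the preferred-reference
    block whose members lie nearest — and a warning is returned for the rest.
    """
    orphans = orphans or set()
    claims: dict[str, list[tuple[int, float, str, OrthologueRecord]]] = {}
    files: dict[str, list[OrthologueRecord]] = {b.block_id: [] for b in blocks}
    warnings: list[str] = []
    for b in blocks:
        if b.is_gap:
            continue
        genes = [g for g in annotation.get(b.ref_genome, [])
                 if g.ref_chromosome == b.ref_chromosome
                 and b.ref_start_bp <= g.ref_bp <= b.ref_end_bp
                 and g.locus not in orphans]
        if not genes:
            warnings.append(f"block {b.block_id}: no annotation genes in extent")
            continue
        pref_rank = preference.index(b.ref_genome) if b.ref_genome in preference else 99
        bps = b.member_bps()
        centre = 0.5 * (min(bps) + max(bps)) if bps else 0.5 * (b.ref_start_bp + b.ref_end_bp)
        for g in genes:
            claims.setdefault(g.locus, []).append(
                (pref_rank, abs(g.ref_bp - centre), b.block_id, g)
            )
    for locus, cands in claims.items():
        cands.sort(key=lambda t: (t[0], t[1], t[2]))
        best = cands[0]
        files[best[2]].append(best[3])
        for other in cands[1:]:
            warnings.append(f"{locus}: also falls in block {other[2]}; kept in {best[2]}")
    for bid in files:
        files[bid].sort(key=lambda g: g.ref_bp)
    return files, warnings


def block_anchor_pairs(block: SyntenyBlock, integrated: list[MapEntry],
                       ref_bp_of: dict[str, float]) -> list[tuple[float, float]]:
    """(ref_bp, kb) anchor pairs for interpolation inside one block:
    the block boundaries plus every integrated locus of the block with a
    known reference position, thinned to a monotone set."""
    if block.target_start_kb is None:
        raise ValidationError(f"block {block.block_id} has no target extent")
    reverse = block.orientation == "reverse"
    pairs = [(block.ref_start_bp, block.target_end_kb if reverse else block.target_start_kb),
             (block.ref_end_bp, block.target_start_kb if reverse else block.target_end_kb)]
    kb_of = {e.locus: e.kb for e in integrated}
    member_names = {m.locus for m in block.members}
    for name in member_names | {n for n in ref_bp_of if is_landmark(n)}:
        if name in kb_of and name in ref_bp_of:
            bp = ref_bp_of[name]
            if block.ref_start_bp <= bp <= block.ref_end_bp:
                pairs.append((bp, kb_of[name]))
    pairs.sort(key=lambda t: t[0])
    # thin to kb-monotone (decreasing for reverse blocks), keeping boundaries
    out = [pairs[0]]
    for bp, kb in pairs[1:-1]:
        ok = kb <= out[-1][1] if reverse else kb >= out[-1][1]
        if ok and bp > out[-1][0]:
            out.append((bp, kb))
    if pairs[-1][0] > out[-1][0]:
        out.append(pairs[-1])
    return out


def interpolate_block_genes(
    block: SyntenyBlock,
    genes: list[OrthologueRecord],
    integrated: list[MapEntry],
    ref_bp_of: dict[str, float],
    frame: ChromosomeFrame,
) -> list[MapEntry]:
    """Place unmapped genes of one block into the map.

    Genes already present in the integrated map are skipped (their
    confidence-2 entries are the backbone and are never moved).
    """
    anchors = block_anchor_pairs(block, integrated, ref_bp_of)
    cm_anchors = _cm_anchors(integrated)
    mapped = {e.locus for e in integrated} | {e.external_id for e in integrated if e.external_id}
    out: list[MapEntry] = []
    for g in genes:
        if g.locus in mapped:
            continue
        if not (block.ref_start_bp - 1e-6 <= g.ref_bp <= block.ref_end_bp + 1e-6):
            raise ValidationError(
                f"{g.locus}: ref_bp {g.ref_bp} outside block {block.block_id} extent"
            )
        kb = _affine(anchors, g.ref_bp)
        kb = min(max(kb, 0.0), frame.spec.size_kb)
        cm = interpolate_cm(kb, cm_anchors)
        conf = assign_confidence(g.locus, {e.locus for e in integrated}, block.orientation)
        out.append(MapEntry(locus=g.locus, external_id=g.locus, kb=kb, cm=cm,
                            band=frame.band_of(kb), confidence=conf,
                            source="interpolated"))
    return out


def _affine(anchors: list[tuple[float, float]], bp: float) -> float:
    for (x0, y0), (x1, y1) in zip(anchors, anchors[1:]):
        if x0 - 1e-9 <= bp <= x1 + 1e-9:
            if x1 == x0:
                return y0
            return y0 + (bp - x0) / (x1 - x0) * (y1 - y0)
    # outside anchored span (extent padding): clamp to the nearer end
    return anchors[0][1] if bp < anchors[0][0] else anchors[-1][1]


def _cm_anchors(integrated: list[MapEntry]) -> list[tuple[float, float]]:
    pts = sorted({(e.kb, e.cm) for e in integrated})
    out = [pts[0]]
    for kb, cm in pts[1:]:
        if kb > out[-1][0] + 1e-9:
            out.append((kb, cm))
    return out


def assign_confidence(locus: str, integrated_loci: set[str], block_orientation: str
                      ) -> int | None:
    """2 if mapped in the target species, 1 in an oriented block, else 0;
    landmarks get None (printed NA)."""
    if is_landmark(locus):
        return None
    if locus in integrated_loci:
        return 2
    return 1 if block_orientation in ("forward", "reverse") else 0


def build_virtual_map(
    frame: ChromosomeFrame,
    integrated: list[MapEntry],
    blocks: list[SyntenyBlock],
    annotation: dict[str, list[OrthologueRecord]],
    ref_bp_by_genome: dict[str, dict[str, float]],
    orphans: set[str] | None = None,
    preference: tuple[str, ...] = ("MDO", "HSA"),
) -> tuple[list[MapEntry], list[str]]:
    """Full virtual map of one chromosome: integrated backbone plus all
    interpolated block genes, sorted by kb (backbone entries unchanged).

    ``ref_bp_by_genome`` maps reference-genome label -> {locus: ref_bp} for
    the loci already in the integrated map (used as within-block anchors).
    """
    files, warnings = build_orthologue_files(blocks, annotation, orphans, preference)
    entries = list(integrated)
    for b in blocks:
        if b.is_gap:
            continue
        entries.extend(interpolate_block_genes(b, files[b.block_id], integrated,
                                               ref_bp_by_genome.get(b.ref_genome, {}),
                                               frame))
    entries.sort(key=lambda e: (e.kb, e.cm, e.locus))
    return entries, warnings


def anchor_scaffolds(
    scaffold_genes: dict[str, list[str]],
    vmap_by_chromosome: dict[str, list[MapEntry]],
    scaffold_lengths_bp: dict[str, int] | None = None,
) -> tuple[list[ScaffoldAnchor], dict[str, float]]:
    """Anchor gene-scaffolds to chromosomes via genes shared with the
    virtual map.

    Returns anchors for scaffolds whose map genes agree on one chromosome,
    plus a summary: counts of scaffolds with exactly one / more than one map
    gene, ambiguous (multi-chromosome) scaffolds, and total anchored bp when
    scaffold lengths are supplied.
    """
    gene_pos: dict[str, tuple[str, float]] = {}
    for chrom, entries in vmap_by_chromosome.items():
        for e in entries:
            for key in (e.locus, e.external_id):
                if key and not is_landmark(key):
                    gene_pos.setdefault(key, (chrom, e.kb))
    anchors: list[ScaffoldAnchor] = []
    n_one = n_multi = n_ambiguous = 0
    anchored_bp = 0
    for sid in sorted(scaffold_genes):
        hits = [(g, *gene_pos[g]) for g in scaffold_genes[sid] if g in gene_pos]
        if not hits:
            continue
        chroms = {h[1] for h in hits}
        if len(chroms) > 1:
            n_ambiguous += 1
            continue
        kbs = [h[2] for h in hits]
        if len(hits) == 1:
            n_one += 1
            orientation = "unknown"
        else:
            n_multi += 1
            if all(b > a for a, b in zip(kbs, kbs[1:])):
                orientation = "forward"
            elif all(b < a for a, b in zip(kbs, kbs[1:])):
                orientation = "reverse"
            else:
                orientation = "unknown"
        anchors.append(ScaffoldAnchor(sid, hits[0][1], min(kbs), max(kbs),
                                      orientation, len(hits)))
        if scaffold_lengths_bp and sid in scaffold_lengths_bp:
            anchored_bp += scaffold_lengths_bp[sid]
    summary = {
        "scaffolds_one_gene": n_one,
        "scaffolds_multi_gene": n_multi,
        "scaffolds_anchored": n_one + n_multi,
        "scaffolds_ambiguous": n_ambiguous,
        "anchored_bp": anchored_bp,
    }
    return anchors, summary
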