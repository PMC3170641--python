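"""Conserved-synteny block and evolutionary-breakpoint detection.

Markers FISH-ordered along a target chromosome, each carrying orthologue
coordinates in one or more reference genomes, are partitioned into blocks of
conserved content.  Because FISH gives only coarse target order (markers in
one band are unordered) while reference coordinates are exact, detection
works reference-space first:

1. markers are grouped by reference chromosome (preferred genome first) and
   clustered wherever consecutive reference positions are within a gap
   limit — content separated by a larger gap has moved elsewhere, which is a
   breakpoint;
2. a cluster whose members occupy two target regions with another cluster's
   markers in between is split (an insertion landed inside it);
3. a cluster whose FISH order reverses direction against its reference
   order is split at the reversal (an inversion); a lone marker off the
   trend beyond the orphan window is excluded as an "orphan" and reported;
4. surviving single-marker clusters lying strictly inside another block's
   FISH span contradict their surroundings and become orphans; singletons
   that could not be resolved in the preferred reference are retried in the
   fallback genome;
5. blocks are ordered along the chromosome by mean FISH position and
   oriented by the trend of FISH order against reference position
   (ascending = forward, descending = reverse, single-band = unknown).

Block reference extents estimate conserved content; summed per chromosome
and rescaled to the chromosome's physical length they give each breakpoint
a kb location.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .records import BreakpointEntry


@dataclass
class Marker:
    """A FISH-mapped target locus with per-reference orthologue coordinates.

    ``fish_order`` is the locus's position in the cytogenetic order along the
    target chromosome (typically the index of its band); markers sharing a
    value are unordered by FISH.  ``orthologues`` maps reference-genome
    label -> (ref_chromosome, ref_bp).
    """

    locus: str
    chromosome: str
    fish_order: float
    orthologues: dict[str, tuple[str, float]] = field(default_factory=dict)
    band: str | None = None
    # True when the order value is FISH-resolved below band resolution
    # (co-hybridised probes ordered directly); False for band-level
    # assignments whose sub-band order component is arbitrary
    order_resolved: bool = False

    def coord(self, ref: str) -> tuple[str, float] | None:
        return self.orthologues.get(ref)


@dataclass
class SyntenyBlock:
    block_id: str
    target_chromosome: str
    ref_genome: str
    ref_chromosome: str
    ref_start_bp: float
    ref_end_bp: float
    orientation: str  # forward | reverse | unknown
    members: list[Marker] = field(default_factory=list)
    target_start_kb: float | None = None
    target_end_kb: float | None = None
    is_gap: bool = False
    gap_span_kb: float | None = None

    @property
    def ref_size_bp(self) -> float:
        return self.ref_end_bp - self.ref_start_bp

    def member_bps(self) -> list[float]:
        """Members' reference positions in target order."""
        return [m.coord(self.ref_genome)[1] for m in self.members]


@dataclass
class OrphanReport:
    locus: str
    reason: str
    block_id: str = ""


def _block_label(i: int) -> str:
    letters = string.ascii_uppercase
    if i < 26:
        return letters[i]
    return letters[i // 26 - 1] + letters[i % 26]


@dataclass
class _Cluster:
    genome: str
    ref_chrom: str
    members: list[Marker]  # sorted by ref_bp ascending

    def bps(self) -> list[float]:
        return [m.coord(self.genome)[1] for m in self.members]

    def orders(self) -> list[float]:
        return [m.fish_order for m in self.members]

    def mean_order(self) -> float:
        return float(np.mean(self.orders()))


def detect_blocks(
    markers: list[Marker],
    preference: tuple[str, ...] = ("MDO", "HSA"),
    orphan_window_bp: float = 10e6,
    max_gap_bp: float = 25e6,
) -> tuple[list[SyntenyBlock], list[OrphanReport]]:
    """Partition FISH-ordered markers into conserved-synteny blocks.

    Returns blocks in target order plus the orphan report.  Markers with no
    reference coordinate in any genome are reported as unplaceable.
    """
    if not markers:
        return [], []
    chroms = {m.chromosome for m in markers}
    orphans_all: list[OrphanReport] = []
    blocks_all: list[SyntenyBlock] = []
    per_chrom: dict[str, list[SyntenyBlock]] = {}
    for chrom in sorted(chroms):
        b = _detect_one(
            [m for m in markers if m.chromosome == chrom],
            preference, max_gap_bp, orphans_all)
        per_chrom[chrom] = b
        blocks_all.extend(b)
    # cross-chromosome reconciliation must see singletons: an end marker cut
    # off by a sampling void rejoins its block here
    reconcile_gaps(blocks_all, max_gap_bp)
    final: list[SyntenyBlock] = []
    for chrom in sorted(chroms):
        b = [blk for blk in blocks_all if blk.target_chromosome == chrom]
        b = _orphan_singleton_blocks(b, orphans_all, orphan_window_bp)
        b = _merge_singletons(b, max_gap_bp)
        for i, blk in enumerate(b):
            blk.block_id = f"{chrom}.{_block_label(i)}"
        _assign_extents(b, max_gap_bp=max_gap_bp)
        final.extend(b)
    return final, orphans_all


def _detect_one(markers: list[Marker], preference: tuple[str, ...],
                max_gap_bp: float, orphans: list[OrphanReport]) -> list[SyntenyBlock]:
    """Chain, split and order the blocks of a single chromosome (singleton
    resolution and extents are finalised genome-wide by the caller)."""
    chrom = markers[0].chromosome
    usable: list[Marker] = []
    for m in markers:
        if m.orthologues:
            usable.append(m)
        else:
            orphans.append(OrphanReport(m.locus, "no reference coordinate in any genome"))
    if not usable:
        return []

    def working(m: Marker) -> str:
        for ref in preference:
            if ref in m.orthologues:
                return ref
        return next(iter(m.orthologues))

    groups: dict[tuple[str, str], list[Marker]] = {}
    for m in usable:
        g = working(m)
        groups.setdefault((g, m.coord(g)[0]), []).append(m)

    parts: list[_Cluster] = []
    for (genome, rc), ms in groups.items():
        ms.sort(key=lambda m: (m.coord(genome)[1], m.locus))
        resolved = [m for m in ms if m.order_resolved]
        if len(resolved) >= 2:
            parts.extend(_skeleton_clusters(genome, rc, ms, resolved, max_gap_bp))
        else:
            parts.extend(_extract_chains(genome, rc, ms, max_gap_bp))

    parts = _split_interleaved(parts, max_gap_bp)
    parts = _fallback_pairs(parts, preference, max_gap_bp)
    if not parts:
        return []
    parts.sort(key=lambda c: (c.mean_order(), min(c.orders()), c.ref_chrom,
                              c.bps()[0]))
    blocks = [_make_block(c, chrom) for c in parts]
    _assign_extents(blocks, max_gap_bp=max_gap_bp)
    return blocks


def _skeleton_clusters(genome: str, rc: str, ms: list[Marker],
                       resolved: list[Marker], max_gap: float) -> list[_Cluster]:
    """Cluster one reference chromosome's markers around its resolved
    skeleton.

    Resolved markers carry trustworthy FISH order; walking them in reference
    order, each sustained direction change is a rearrangement boundary.  At
    a peak (order rises then falls) the vertex marker opens the falling run
    — it is the target-distal end of an inverted segment; at a valley the
    vertex closes the falling run for the same reason.  Band-level markers
    then join the run whose reference interval holds them, and residual
    reference gaps larger than ``max_gap`` still split.
    """
    runs: list[list[Marker]] = []
    cur = [resolved[0]]
    direction = 0
    for m in resolved[1:]:
        step = np.sign(m.fish_order - cur[-1].fish_order)
        if step == 0 or direction == 0 or step == direction:
            if direction == 0 and step != 0:
                direction = int(step)
            cur.append(m)
            continue
        # direction change: the vertex marker joins whichever side it is
        # closer to in FISH order — an inverted segment's terminal probe is
        # order-close to the segment's interior, while a junction jumping to
        # a distant part of the chromosome leaves the vertex with its run
        vertex = cur[-1]
        prev_val = cur[-2].fish_order if len(cur) >= 2 else None
        go_new = (prev_val is None
                  or abs(vertex.fish_order - m.fish_order)
                  <= abs(vertex.fish_order - prev_val))
        if go_new:
            cur.pop()
            if cur:
                runs.append(cur)
            cur = [vertex, m]
        else:
            runs.append(cur)
            cur = [m]
        direction = int(step)
    runs.append(cur)

    intervals = [(min(m.coord(genome)[1] for m in r),
                  max(m.coord(genome)[1] for m in r)) for r in runs]
    for m in ms:
        if m.order_resolved:
            continue
        bp = m.coord(genome)[1]
        best_i, best_d = 0, None
        for i, (lo, hi) in enumerate(intervals):
            d = 0.0 if lo <= bp <= hi else min(abs(bp - lo), abs(bp - hi))
            if best_d is None or d < best_d:
                best_i, best_d = i, d
        runs[best_i].append(m)

    clusters: list[_Cluster] = []
    for r in runs:
        r.sort(key=lambda m: (m.coord(genome)[1], m.locus))
        clusters.extend(_gap_split(genome, rc, r, max_gap))
    return clusters


def _gap_split(genome: str, rc: str, ms: list[Marker], max_gap: float) -> list[_Cluster]:
    out = []
    cur = [ms[0]]
    for m in ms[1:]:
        if m.coord(genome)[1] - cur[-1].coord(genome)[1] > max_gap:
            out.append(_Cluster(genome, rc, cur))
            cur = [m]
        else:
            cur.append(m)
    out.append(_Cluster(genome, rc, cur))
    return out


def _extract_chains(genome: str, rc: str, ms: list[Marker], max_gap: float,
                    max_order_jump: float = 1.1) -> list[_Cluster]:
    """Chain markers of one reference chromosome into conserved runs.

    Walking markers in reference order, a marker extends the open chain
    that is nearest in FISH order, provided the reference gap is within
    ``max_gap``, the FISH-order step is within ``max_order_jump`` and its
    sign matches the chain's established direction.  Interleaved target
    segments sharing one reference region thus separate into their own
    chains (the sparse-anchor analogue of diagonal runs in a dot plot).
    """
    chains: list[dict] = []
    for m in ms:
        bp = m.coord(genome)[1]
        best = None
        for ch in chains:
            gap = bp - ch["last_bp"]
            if gap > max_gap:
                continue
            dorder = m.fish_order - ch["last_order"]
            if abs(dorder) > max_order_jump:
                continue
            # single sub-band steps carry no direction, but cumulative drift
            # against the chain's trend (past its running extreme by about a
            # band) is a reversal: refuse the attachment
            if ch["direction"] > 0 and m.fish_order < ch["max_order"] - 0.9:
                continue
            if ch["direction"] < 0 and m.fish_order > ch["min_order"] + 0.9:
                continue
            score = (abs(dorder), gap)
            if best is None or score < best[0]:
                best = (score, ch)
        if best is None:
            chains.append({"members": [m], "direction": 0,
                           "last_bp": bp, "last_order": m.fish_order,
                           "first_order": m.fish_order,
                           "min_order": m.fish_order, "max_order": m.fish_order})
        else:
            ch = best[1]
            ch["members"].append(m)
            ch["last_bp"] = bp
            ch["last_order"] = m.fish_order
            ch["min_order"] = min(ch["min_order"], m.fish_order)
            ch["max_order"] = max(ch["max_order"], m.fish_order)
            if ch["direction"] == 0 and abs(m.fish_order - ch["first_order"]) >= 0.9:
                ch["direction"] = int(np.sign(m.fish_order - ch["first_order"]))
    return [_Cluster(genome, rc, ch["members"]) for ch in chains]


def _split_interleaved(clusters: list[_Cluster], max_gap: float = 25e6) -> list[_Cluster]:
    """Split a chain occupying two disjoint FISH spans with foreign markers
    strictly in between (it bridged across an inserted segment).

    Only genuinely foreign content counts as evidence: markers of another
    reference chromosome, or of the same chromosome but from a reference
    region further than the gap limit — a sibling piece cut off by a
    sampling void sits in the same bands and must not split its own block.
    """
    work = list(clusters)
    changed = True
    while changed:
        changed = False
        for idx, c in enumerate(work):
            c_lo, c_hi = c.bps()[0], c.bps()[-1]
            others = []
            for j, cl in enumerate(work):
                if j == idx:
                    continue
                if (cl.genome, cl.ref_chrom) == (c.genome, c.ref_chrom):
                    o_lo, o_hi = cl.bps()[0], cl.bps()[-1]
                    if max(c_lo, o_lo) - min(c_hi, o_hi) <= 2 * max_gap:
                        continue  # ref-nearby sibling: not insertion evidence
                others.extend(cl.members)
            other_orders = [m.fish_order for m in others]
            cut = None
            orders = sorted(set(c.orders()))
            for o1, o2 in zip(orders, orders[1:]):
                if (o2 - o1 >= 0.95
                        and any(o1 + 0.02 < x < o2 - 0.02 for x in other_orders)):
                    cut = 0.5 * (o1 + o2)
                    break
            low = high = None
            if cut is not None:
                low = [m for m in c.members if m.fish_order < cut]
                high = [m for m in c.members if m.fish_order >= cut]
            else:
                # resolved-vs-resolved order is trustworthy at any scale: a
                # foreign resolved probe strictly between two consecutive
                # resolved members proves the cluster is interrupted there
                res = sorted(m.fish_order for m in c.members if m.order_resolved)
                foreign_res = [m.fish_order for m in others if m.order_resolved]
                for a, b in zip(res, res[1:]):
                    if b - a > 0.05 and any(a + 0.01 < x < b - 0.01
                                            for x in foreign_res):
                        low, high = _split_by_resolved_sides(c, 0.5 * (a + b))
                        break
            if low and high:
                work[idx:idx + 1] = [_Cluster(c.genome, c.ref_chrom, low),
                                     _Cluster(c.genome, c.ref_chrom, high)]
                changed = True
            if changed:
                break
    return work


def _split_by_resolved_sides(c: _Cluster, cut: float):
    """Split a cluster at an order cut between resolved members; band-level
    members follow the side whose resolved reference interval is nearest
    (their own sub-band order is arbitrary and cannot be trusted)."""
    low_res = [m for m in c.members if m.order_resolved and m.fish_order < cut]
    high_res = [m for m in c.members if m.order_resolved and m.fish_order >= cut]
    if not low_res or not high_res:
        return ([m for m in c.members if m.fish_order < cut],
                [m for m in c.members if m.fish_order >= cut])

    def interval(ms):
        bps = [m.coord(c.genome)[1] for m in ms]
        return min(bps), max(bps)

    lo_iv, hi_iv = interval(low_res), interval(high_res)
    low, high = list(low_res), list(high_res)
    for m in c.members:
        if m.order_resolved:
            continue
        bp = m.coord(c.genome)[1]
        d_lo = 0.0 if lo_iv[0] <= bp <= lo_iv[1] else min(abs(bp - lo_iv[0]),
                                                          abs(bp - lo_iv[1]))
        d_hi = 0.0 if hi_iv[0] <= bp <= hi_iv[1] else min(abs(bp - hi_iv[0]),
                                                          abs(bp - hi_iv[1]))
        (low if d_lo <= d_hi else high).append(m)
    low.sort(key=lambda m: m.coord(c.genome)[1])
    high.sort(key=lambda m: m.coord(c.genome)[1])
    return low, high


def _fallback_pairs(parts: list[_Cluster], preference: tuple[str, ...],
                    max_gap: float) -> list[_Cluster]:
    """Singletons unresolved in the preferred genome may pair up in the
    fallback: accept a fallback run of >= 2 only from markers that formed no
    preferred run."""
    if len(preference) < 2:
        return parts
    fallback = preference[1]
    singles = [c for c in parts if len(c.members) == 1
               and c.genome == preference[0]
               and fallback in c.members[0].orthologues]
    if len(singles) < 2:
        return parts
    by_chrom: dict[str, list[_Cluster]] = {}
    for c in singles:
        by_chrom.setdefault(c.members[0].coord(fallback)[0], []).append(c)
    merged: dict[int, _Cluster] = {}
    for rc, cs in by_chrom.items():
        if len(cs) < 2:
            continue
        cs.sort(key=lambda c: c.members[0].coord(fallback)[1])
        run: list[_Cluster] = [cs[0]]
        groups = []
        for c in cs[1:]:
            if (c.members[0].coord(fallback)[1]
                    - run[-1].members[0].coord(fallback)[1] <= max_gap):
                run.append(c)
            else:
                groups.append(run)
                run = [c]
        groups.append(run)
        for g in groups:
            if len(g) >= 2:
                members = sorted((c.members[0] for c in g),
                                 key=lambda m: m.coord(fallback)[1])
                new = _Cluster(fallback, rc, members)
                for c in g:
                    merged[id(c)] = new
    out, seen = [], set()
    for c in parts:
        if id(c) in merged:
            if id(merged[id(c)]) not in seen:
                out.append(merged[id(c)])
                seen.add(id(merged[id(c)]))
        else:
            out.append(c)
    return out


def _orphan_singleton_blocks(blocks: list[SyntenyBlock], orphans: list[OrphanReport],
                             orphan_window: float) -> list[SyntenyBlock]:
    """Resolve lone markers lying strictly inside another block's FISH span.

    Such a marker contradicts the surrounding run: if it sits on the same
    reference chromosome within ``orphan_window`` of the position the run's
    trend predicts for it, it is absorbed back into the run (local jitter);
    otherwise it is an orphan and excluded.
    """
    def orders(b: SyntenyBlock) -> list[float]:
        return [m.fish_order for m in b.members]

    keep = []
    for b in blocks:
        if len(b.members) > 1 or b.is_gap:
            keep.append(b)
            continue
        m = b.members[0]
        o = m.fish_order
        covering = [other for other in blocks
                    if other is not b and len(other.members) >= 2
                    and min(orders(other)) < o < max(orders(other))]
        if not covering:
            keep.append(b)
            continue
        host = None
        for other in covering:
            if (other.ref_genome != b.ref_genome
                    or other.ref_chromosome != b.ref_chromosome):
                continue
            pts = sorted((mm.fish_order, mm.coord(other.ref_genome)[1])
                         for mm in other.members)
            expected = float(np.interp(o, [p[0] for p in pts], [p[1] for p in pts]))
            if abs(m.coord(b.ref_genome)[1] - expected) <= orphan_window:
                host = other
                break
        if host is not None:
            host.members.append(m)
            host.members.sort(key=lambda mm: mm.coord(host.ref_genome)[1],
                              reverse=host.orientation == "reverse")
            bp = m.coord(host.ref_genome)[1]
            host.ref_start_bp = min(host.ref_start_bp, bp)
            host.ref_end_bp = max(host.ref_end_bp, bp)
        else:
            orphans.append(OrphanReport(
                m.locus,
                f"single {b.ref_genome}:{b.ref_chromosome} marker contradicts "
                "the surrounding block"))
    return keep


def _make_block(c: _Cluster, chrom: str) -> SyntenyBlock:
    bps = c.bps()
    orders = c.orders()
    orientation = "unknown"
    if len(c.members) >= 2 and len(set(orders)) >= 2:
        slope = float(np.sum((np.array(bps) - np.mean(bps))
                             * (np.array(orders) - np.mean(orders))))
        if slope > 0:
            orientation = "forward"
        elif slope < 0:
            orientation = "reverse"
    members = sorted(c.members,
                     key=lambda m: (m.fish_order,
                                    m.coord(c.genome)[1]
                                    * (-1 if orientation == "reverse" else 1)))
    return SyntenyBlock(
        block_id="",
        target_chromosome=chrom,
        ref_genome=c.genome,
        ref_chromosome=c.ref_chrom,
        ref_start_bp=min(bps),
        ref_end_bp=max(bps),
        orientation=orientation,
        members=members,
    )


def _merge_singletons(blocks: list[SyntenyBlock], max_gap: float) -> list[SyntenyBlock]:
    """Absorb single-member blocks into an adjacent block of the same
    reference chromosome when the lone marker continues that block's
    monotone run within the gap limit."""
    changed = True
    while changed:
        changed = False
        for i, b in enumerate(blocks):
            if len(b.members) != 1 or b.is_gap:
                continue
            bp = b.member_bps()[0]
            for j, append in ((i - 1, True), (i + 1, False)):
                if not (0 <= j < len(blocks)):
                    continue
                nb = blocks[j]
                if (nb.is_gap or nb.ref_genome != b.ref_genome
                        or nb.ref_chromosome != b.ref_chromosome):
                    continue
                nb_bps = nb.member_bps()
                terminal = nb_bps[-1] if append else nb_bps[0]
                if abs(bp - terminal) > max_gap:
                    continue
                merged_bps = nb_bps + [bp] if append else [bp] + nb_bps
                diffs = np.sign(np.diff(merged_bps))
                if len({d for d in diffs if d != 0}) > 1:
                    continue  # would break monotonicity
                nb.members = (nb.members + b.members) if append else (b.members + nb.members)
                nb.ref_start_bp = min(nb.ref_start_bp, bp)
                nb.ref_end_bp = max(nb.ref_end_bp, bp)
                del blocks[i]
                changed = True
                break
            if changed:
                break
    return blocks


def _assign_extents(blocks: list[SyntenyBlock], min_block_bp: float = 1e6,
                    max_gap_bp: float = 25e6) -> None:
    """Estimate each block's reference extent (a proxy for its conserved
    content).

    A boundary shared with a neighbouring block on the same reference
    chromosome, with terminal members within ``max_gap_bp`` of each other,
    is placed at their midpoint.  Other boundaries (chromosome changes,
    large reference gaps whose content has moved elsewhere, chromosome
    ends) stay at the terminal member's position: FISH probe selection
    deliberately targets breakpoint-flanking genes, so terminal markers are
    treated as block ends.  Every extent is floored at ``min_block_bp``.
    """
    for i, b in enumerate(blocks):
        lo, hi = b.ref_start_bp, b.ref_end_bp
        bps = b.member_bps()
        for j, side in ((i - 1, "left"), (i + 1, "right")):
            own_terminal = bps[-1 if side == "right" else 0]
            mid = None
            if 0 <= j < len(blocks):
                nb = blocks[j]
                if (not nb.is_gap and nb.ref_genome == b.ref_genome
                        and nb.ref_chromosome == b.ref_chromosome):
                    nb_terminal = nb.member_bps()[0 if side == "right" else -1]
                    if abs(own_terminal - nb_terminal) <= max_gap_bp:
                        mid = 0.5 * (own_terminal + nb_terminal)
            edge = mid if mid is not None else own_terminal
            lo, hi = min(lo, edge), max(hi, edge)
        lo = max(lo, 0.0)
        if hi - lo < min_block_bp:
            pad = 0.5 * (min_block_bp - (hi - lo))
            lo, hi = max(0.0, lo - pad), hi + pad
            if hi - lo < min_block_bp:  # clipped at 0
                hi = lo + min_block_bp
        b.ref_start_bp, b.ref_end_bp = lo, hi


def reconcile_gaps(blocks: list[SyntenyBlock], max_gap_bp: float = 25e6) -> None:
    """Genome-wide resolution of large reference gaps between neighbouring
    blocks of one chromosome.

    Two target-adjacent blocks on the same reference chromosome separated by
    a big reference gap mean either that the intervening content moved to
    another chromosome (a real breakpoint) or that no marker happened to be
    sampled there.  If no block anywhere else in the genome covers the gap
    interval, the content has nowhere else to be: the two blocks are merged
    and the false breakpoint disappears.
    """
    by_chrom: dict[str, list[int]] = {}
    for i, b in enumerate(blocks):
        by_chrom.setdefault(b.target_chromosome, []).append(i)
    to_remove: set[int] = set()
    for chrom, idxs in by_chrom.items():
        k = 0
        while k < len(idxs) - 1:
            i, j = idxs[k], idxs[k + 1]
            a, b = blocks[i], blocks[j]
            if (a.is_gap or b.is_gap or a.ref_genome != b.ref_genome
                    or a.ref_chromosome != b.ref_chromosome):
                k += 1
                continue
            gap_lo = min(a.ref_end_bp, b.ref_end_bp)
            gap_hi = max(a.ref_start_bp, b.ref_start_bp)
            if gap_hi - gap_lo <= max_gap_bp:
                k += 1
                continue
            claimed_elsewhere = any(
                other is not a and other is not b and not other.is_gap
                and other.ref_genome == a.ref_genome
                and other.ref_chromosome == a.ref_chromosome
                and any(gap_lo < bp < gap_hi for bp in other.member_bps())
                for other in blocks
            )
            if claimed_elsewhere:
                k += 1
                continue
            # unclaimed gap: sampling artifact, merge the two blocks and
            # rebuild orientation from the merged FISH-vs-reference trend
            rebuilt = _make_block(
                _Cluster(a.ref_genome, a.ref_chromosome,
                         sorted(a.members + b.members,
                                key=lambda m: m.coord(a.ref_genome)[1])),
                chrom)
            a.members = rebuilt.members
            a.orientation = rebuilt.orientation
            a.ref_start_bp = min(a.ref_start_bp, b.ref_start_bp)
            a.ref_end_bp = max(a.ref_end_bp, b.ref_end_bp)
            to_remove.add(j)
            del idxs[k + 1]
    for j in sorted(to_remove, reverse=True):
        del blocks[j]


def gap_block(target_chromosome: str, span_kb: float, block_id: str = "gap") -> SyntenyBlock:
    """An explicit unassignable region: no members, unknown orientation,
    fixed target span absorbed during scaling."""
    return SyntenyBlock(
        block_id=block_id, target_chromosome=target_chromosome, ref_genome="",
        ref_chromosome="", ref_start_bp=0.0, ref_end_bp=span_kb * 1000.0,
        orientation="unknown", members=[], is_gap=True, gap_span_kb=span_kb,
    )


def block_sizes_ref(blocks: list[SyntenyBlock]) -> list[float]:
    """Reference size (bp) of each block: end - start of its extent."""
    return [b.ref_size_bp for b in blocks]


def scale_to_target(blocks: list[SyntenyBlock], chromosome_size_mb: float
                    ) -> tuple[list[SyntenyBlock], list[BreakpointEntry]]:
    """Scale cumulative block sizes onto the target chromosome.

    Gap blocks (``is_gap``) occupy their fixed ``gap_span_kb``; the remaining
    length is shared among real blocks proportionally to their reference
    sizes.  Internal block boundaries become breakpoints (blocks - 1 of them).
    """
    size_kb = chromosome_size_mb * 1000.0
    gap_kb = sum(b.gap_span_kb or 0.0 for b in blocks if b.is_gap)
    total_ref = sum(b.ref_size_bp for b in blocks if not b.is_gap)
    if total_ref <= 0 and gap_kb < size_kb:
        raise ValidationError("zero total block size: cannot scale to target")
    scale = (size_kb - gap_kb) / total_ref if total_ref > 0 else 0.0
    pos = 0.0
    breakpoints: list[BreakpointEntry] = []
    for i, b in enumerate(blocks):
        span = (b.gap_span_kb or 0.0) if b.is_gap else b.ref_size_bp * scale
        b.target_start_kb = pos
        pos = size_kb if i == len(blocks) - 1 else pos + span
        b.target_end_kb = pos
        if i < len(blocks) - 1:
            breakpoints.append(BreakpointEntry(id=f"BREAKPOINT{i + 1}", kb=pos))
    return blocks, breakpoints


def count_blocks(breakpoints_per_chromosome: dict[str, list[BreakpointEntry]]
                 ) -> tuple[dict[str, int], int, float]:
    """Blocks per chromosome (= breakpoints + 1), total, and mean."""
    counts = {}
    for chrom, bps in breakpoints_per_chromosome.items():
        kbs = [b.kb for b in bps]
        if any(b2 <= b1 for b1, b2 in zip(kbs, kbs[1:])):
            raise ValidationError(f"{chrom}: breakpoints not strictly increasing")
        counts[chrom] = len(bps) + 1
    total = sum(counts.values())
    mean = total / len(counts) if counts else 0.0
    return counts, total, mean
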