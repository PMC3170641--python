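"""Conserved-block detection, scaling and breakpoint counting."""

import numpy as np
import pytest

from mapweaver import (
    Marker,
    SimulationConfig,
    ValidationError,
    apply_rearrangements,
    count_blocks,
    detect_blocks,
    gap_block,
    scale_to_target,
    simulate_reference,
)
from mapweaver import reference_data
from mapweaver.synteny import block_sizes_ref


def _markers(spec):
    """Build markers from (locus, order, ref_chrom, ref_mb) tuples."""
    return [Marker(locus=loc, chromosome="T1", fish_order=float(o),
                   orthologues={"MDO": (rc, mb * 1e6)})
            for loc, o, rc, mb in spec]


def test_chromosome_change_splits_blocks():
    blocks, orphans = detect_blocks(_markers([
        ("a", 0, "A", 10), ("b", 1, "A", 20), ("c", 2, "A", 30),
        ("d", 3, "B", 5), ("e", 4, "B", 15),
    ]))
    assert len(blocks) == 2
    assert [b.ref_chromosome for b in blocks] == ["A", "B"]
    assert [len(b.members) for b in blocks] == [3, 2]
    assert not orphans


def test_descending_reference_positions_give_reverse_orientation():
    blocks, _ = detect_blocks(_markers([
        ("a", 0, "A", 10), ("b", 1, "A", 8), ("c", 2, "A", 5),
    ]))
    assert len(blocks) == 1
    assert blocks[0].orientation == "reverse"


def test_single_member_block_has_unknown_orientation_and_floored_extent():
    blocks, _ = detect_blocks(_markers([
        ("a", 0, "A", 10), ("b", 1, "A", 12), ("c", 2, "B", 50),
        ("d", 3, "A", 60), ("e", 4, "A", 62),
    ]))
    single = next(b for b in blocks if b.ref_chromosome == "B")
    assert single.orientation == "unknown"
    assert single.ref_size_bp >= 1e6  # minimum extent floor


def test_lone_contradicting_marker_is_orphaned():
    """A single foreign-chromosome marker inside a consistent run's FISH
    span contradicts the run and is excluded."""
    blocks, orphans = detect_blocks(_markers([
        ("a", 0, "A", 10), ("b", 0.9, "A", 20),
        ("x", 2.0, "B", 99),
        ("c", 1.8, "A", 30), ("d", 2.7, "A", 40),
    ]))
    assert [o.locus for o in orphans] == ["x"]
    assert all("x" not in [m.locus for m in b.members] for b in blocks)


def test_marker_without_any_reference_reported_unplaceable():
    ms = _markers([("a", 0, "A", 10), ("b", 1, "A", 20)])
    ms.append(Marker("z", "T1", 2.0, orthologues={}))
    _, orphans = detect_blocks(ms)
    assert orphans[0].locus == "z"
    assert "no reference" in orphans[0].reason


def test_fallback_reference_pairs_unresolved_singletons():
    """Two neighbours without preferred-genome coordinates pair up in the
    fallback genome."""
    ms = _markers([("a", 0, "A", 10), ("b", 1, "A", 20)])
    ms.append(Marker("f1", "T1", 2.0, orthologues={"HSA": ("H2", 5e6)}))
    ms.append(Marker("f2", "T1", 3.0, orthologues={"HSA": ("H2", 9e6)}))
    blocks, orphans = detect_blocks(ms, preference=("MDO", "HSA"))
    fallback = [b for b in blocks if b.ref_genome == "HSA"]
    assert len(fallback) == 1
    assert {m.locus for m in fallback[0].members} == {"f1", "f2"}


def test_block_sizes_are_extent_differences():
    blocks, _ = detect_blocks(_markers([
        ("a", 0, "A", 10), ("b", 1, "A", 160),
        ("c", 2, "B", 0), ("d", 3, "B", 50),
    ]))
    assert block_sizes_ref(blocks) == [pytest.approx(b.ref_end_bp - b.ref_start_bp)
                                       for b in blocks]


def _block(chrom, ref_chrom, start_mb, end_mb):
    from mapweaver import SyntenyBlock
    return SyntenyBlock(block_id="", target_chromosome=chrom, ref_genome="MDO",
                        ref_chromosome=ref_chrom, ref_start_bp=start_mb * 1e6,
                        ref_end_bp=end_mb * 1e6, orientation="forward")


def test_proportional_scaling_places_breakpoint():
    # extents 150 and 50 Mb -> breakpoint at 3/4 of a 400 Mb chromosome
    blocks = [_block("T1", "A", 10, 160), _block("T1", "B", 0, 50)]
    blocks, bps = scale_to_target(blocks, 400.0)
    assert len(bps) == 1
    assert bps[0].kb == pytest.approx(300000.0)
    assert blocks[-1].target_end_kb == pytest.approx(400000.0)


def test_scaling_matches_cumulative_sum_oracle():
    rng = np.random.default_rng(3)
    sizes = rng.uniform(5, 80, size=6)
    blocks = [_block("T1", f"C{i}", 0, s) for i, s in enumerate(sizes)]
    blocks, bps = scale_to_target(blocks, 500.0)
    scale = 500000.0 / sizes.sum()
    expected = np.cumsum(sizes)[:-1] * scale
    assert [b.kb for b in bps] == pytest.approx(list(expected), abs=1.0)


def test_single_block_yields_no_breakpoints():
    blocks, _ = detect_blocks(_markers([("a", 0, "A", 10), ("b", 1, "A", 50)]))
    _, bps = scale_to_target(blocks, 133.0)
    assert bps == []


def test_gap_block_absorbs_fixed_span():
    blocks, _ = detect_blocks(_markers([("a", 1, "A", 10), ("b", 2, "A", 110)]))
    blocks = [gap_block("T1", 44000.0)] + blocks
    blocks, bps = scale_to_target(blocks, 367.0)
    assert bps[0].kb == pytest.approx(44000.0)
    assert blocks[0].target_end_kb == pytest.approx(44000.0)
    assert blocks[-1].target_end_kb == pytest.approx(367000.0)


def test_block_counts_from_published_breakpoints():
    counts, total, mean = count_blocks(reference_data.tammar_breakpoints())
    assert counts["5"] == 9
    assert counts["3"] == 28
    assert counts["7"] == 2
    assert total == 84
    assert mean == pytest.approx(12.0)


def test_empty_breakpoint_list_means_one_block():
    counts, total, mean = count_blocks({"X": []})
    assert counts["X"] == 1 and total == 1


def test_unsorted_breakpoints_rejected():
    from mapweaver import BreakpointEntry
    with pytest.raises(ValidationError, match="increasing"):
        count_blocks({"1": [BreakpointEntry("b1", 50.0), BreakpointEntry("b2", 40.0)]})


def test_detection_is_idempotent_on_own_members():
    spec = [("a", 0, "A", 10), ("b", 1, "A", 20), ("c", 2, "B", 5),
            ("d", 3, "B", 15), ("e", 4, "A", 90), ("f", 5, "A", 95)]
    blocks, _ = detect_blocks(_markers(spec))
    again, _ = detect_blocks([m for b in blocks for m in b.members])
    assert [(b.ref_chromosome, [m.locus for m in b.members]) for b in blocks] == \
           [(b.ref_chromosome, [m.locus for m in b.members]) for b in again]


def test_rearranged_genome_recovered_with_dense_exact_markers():
    """With every gene as an exactly ordered marker, all applied
    rearrangement boundaries are recovered to within half the inter-gene
    gap."""
    config = SimulationConfig(seed=5, n_chromosomes=3, genes_per_chromosome=300,
                              n_inversions=4, n_translocations=2)
    rng = np.random.default_rng(config.seed)
    reference = simulate_reference(config, rng)
    truth = apply_rearrangements(reference, config, rng)
    info = truth.genes.set_index("gene_id")
    markers = []
    for chrom, sub in truth.genes.groupby("chromosome"):
        sub = sub.sort_values("kb")
        for rank, row in enumerate(sub.itertuples()):
            markers.append(Marker(row.gene_id, chrom, float(rank),
                                  {"REF": (row.ref_chromosome, row.ref_bp)},
                                  order_resolved=True))
    blocks, orphans = detect_blocks(markers, preference=("REF",))
    mean_gap_kb = config.mean_gene_spacing_kb
    found = total = 0
    for chrom in truth.size_kb:
        cblocks = [b for b in blocks if b.target_chromosome == chrom]
        cblocks, bps = scale_to_target(cblocks, truth.size_kb[chrom] / 1000.0)
        inferred = [b.kb for b in bps]
        for t in truth.breakpoints[chrom]:
            total += 1
            if inferred and min(abs(x - t) for x in inferred) <= 2 * mean_gap_kb:
                found += 1
    assert total > 0
    assert found / total == 1.0
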