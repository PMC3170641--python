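"""The integration engine: linkage anchoring, FISH placement, interpolation
and band curation."""

import numpy as np
import pytest

from mapweaver import (
    BandSpec,
    ChromosomeFrame,
    ChromosomeSpec,
    ArmSpec,
    FishAssignment,
    IntegrationError,
    LinkageCoverage,
    LinkageEntry,
    Marker,
    SyntenyBlock,
    ValidationError,
    curate_bands,
    integrate_chromosome,
    interpolate_cm,
    refine_with_orthologues,
    rescale_linkage,
    seed_fish_positions,
)


# ---------------------------------------------------------------------------
# linkage rescaling

def test_offset_arithmetic():
    cov = LinkageCoverage("5", map_length_cm=50.0, m_percent=3.0)
    assert cov.offset_cm == pytest.approx(1.5)
    out = rescale_linkage([LinkageEntry("A", 10.0, 10.0)], cov, 60.0)
    by = {e.locus: e for e in out}
    assert by["A"].cm == pytest.approx(11.5)
    assert by["ptr"].cm == 0.0
    assert by["qtr"].cm == pytest.approx(60.0)


def test_zero_m_percent_is_identity_shift():
    cov = LinkageCoverage("1", 100.0, 0.0)
    out = rescale_linkage([LinkageEntry("A", 42.0, 42.0)], cov, 120.0)
    assert {e.locus: e.cm for e in out}["A"] == pytest.approx(42.0)


def test_rescaling_preserves_map_span():
    rng = np.random.default_rng(2)
    cov = LinkageCoverage("1", 80.0, 12.0)
    cms = np.sort(rng.uniform(0, 80, 15))
    out = rescale_linkage([LinkageEntry(f"L{i}", c, c) for i, c in enumerate(cms)],
                          cov, 120.0)
    shifted = [e.cm for e in out if e.locus.startswith("L")]
    assert max(shifted) - min(shifted) == pytest.approx(cms.max() - cms.min())


def test_rescaled_position_beyond_chromosome_rejected():
    cov = LinkageCoverage("1", 100.0, 30.0)
    with pytest.raises(ValidationError, match="exceeds"):
        rescale_linkage([LinkageEntry("A", 95.0, 95.0)], cov, 110.0)


# ---------------------------------------------------------------------------
# FISH seeding and comparative refinement

def test_band_midpoint_seeding(meu5_frame):
    pos = seed_fish_positions([FishAssignment("X", "q1", "q1")], meu5_frame.bands)
    assert pos["X"] == pytest.approx(0.5 * (66812 + 136812))


def test_band_range_midpoint_spans_union(meu5_frame):
    pos = seed_fish_positions([FishAssignment("X", "p3", "p2")], meu5_frame.bands)
    assert pos["X"] == pytest.approx(0.5 * (0 + 46812))


def test_unknown_band_rejected(meu5_frame):
    with pytest.raises(ValidationError, match="unknown band"):
        seed_fish_positions([FishAssignment("X", "p9", "p9")], meu5_frame.bands)


def _refine_block(orientation="forward"):
    members = [Marker("A", "5", 0.0, {"MDO": ("M4", 25e6)}),
               Marker("B", "5", 1.0, {"MDO": ("M4", 75e6)})]
    return SyntenyBlock(block_id="b", target_chromosome="5", ref_genome="MDO",
                        ref_chromosome="M4", ref_start_bp=0.0, ref_end_bp=100e6,
                        orientation=orientation, members=members,
                        target_start_kb=0.0, target_end_kb=100000.0)


def test_orthologue_refinement_affine_placement():
    refined = refine_with_orthologues({"A": 1.0, "B": 2.0}, [_refine_block()])
    assert refined["A"] == pytest.approx(25000.0)
    assert refined["B"] == pytest.approx(75000.0)


def test_orthologue_refinement_flips_in_reverse_blocks():
    refined = refine_with_orthologues({"A": 1.0, "B": 2.0},
                                      [_refine_block("reverse")])
    assert refined["A"] == pytest.approx(75000.0)
    assert refined["B"] == pytest.approx(25000.0)


def test_refinement_clamps_into_assigned_band():
    refined = refine_with_orthologues({"A": 1.0, "B": 2.0}, [_refine_block()],
                                      band_unions={"A": (30000.0, 40000.0)})
    assert refined["A"] == pytest.approx(30000.0)  # 25000 pulled up to the band
    assert refined["B"] == pytest.approx(75000.0)


def test_locus_outside_any_block_keeps_provisional():
    refined = refine_with_orthologues({"Z": 12345.0}, [_refine_block()])
    assert refined["Z"] == 12345.0


# ---------------------------------------------------------------------------
# cM interpolation (published worked rows)

@pytest.mark.parametrize("kb,lo,hi,expected", [
    (293771, "RRM1", "DFFB", 202.37),
    (291421, "PHCA", "CCKBR", 200.83),
    (152272, "ZEB2", "TECTA", 109.57),
    (66989, "cen", "CTPS2", 53.64),
    (67096, "cen", "CTPS2", 53.71),
    (293913, "BREAKPOINT7", "DFFB", 202.46),
    (339581, "LENG8", "qtr", 232.42),
])
def test_interpolation_reproduces_published_cm(published_map, kb, lo, hi, expected):
    anchors = [(published_map[lo].kb, published_map[lo].cm),
               (published_map[hi].kb, published_map[hi].cm)]
    assert round(interpolate_cm(kb, anchors), 2) == pytest.approx(expected)


def test_interpolation_exact_at_anchors():
    anchors = [(0.0, 0.0), (1000.0, 5.0), (2000.0, 9.0)]
    for kb, cm in anchors:
        assert interpolate_cm(kb, anchors) == pytest.approx(cm)


def test_interpolation_matches_two_point_formula_oracle():
    rng = np.random.default_rng(6)
    kbs = np.sort(rng.uniform(0, 300000, 8))
    cms = np.sort(rng.uniform(0, 200, 8))
    anchors = list(zip(kbs, cms))
    for _ in range(50):
        q = rng.uniform(kbs[0], kbs[-1])
        i = np.searchsorted(kbs, q) - 1
        i = max(0, min(i, len(kbs) - 2))
        expected = cms[i] + (q - kbs[i]) / (kbs[i + 1] - kbs[i]) * (cms[i + 1] - cms[i])
        assert interpolate_cm(q, anchors) == pytest.approx(expected)


def test_interpolation_outside_anchored_range_rejected():
    with pytest.raises(ValidationError, match="outside"):
        interpolate_cm(-1.0, [(0.0, 0.0), (100.0, 1.0)])


# ---------------------------------------------------------------------------
# whole-chromosome integration

def _mini_frame():
    spec = ChromosomeSpec("c", 100.0, 50.0)
    arms = [ArmSpec("p", 40.0, 20.0, 20.0), ArmSpec("q", 60.0, 30.0, 30.0)]
    bands = [BandSpec("p2", 20.0, 0.0, 20.0), BandSpec("p1", 20.0, 20.0, 40.0),
             BandSpec("q1", 30.0, 40.0, 70.0), BandSpec("q2", 30.0, 70.0, 100.0)]
    return ChromosomeFrame(spec=spec, arms=arms, bands=bands, centromere_kb=40000.0)


def test_fish_only_map_spans_full_extent():
    frame = _mini_frame()
    fish = [FishAssignment("A", "p2", "p2"), FishAssignment("B", "q2", "q2")]
    entries, conflicts = integrate_chromosome(frame, fish)
    by = {e.locus: e for e in entries}
    assert by["ptr"].kb == 0.0 and by["ptr"].cm == 0.0
    assert by["qtr"].kb == 100000.0 and by["qtr"].cm == pytest.approx(50.0)
    assert 0.0 < by["A"].cm < by["cen"].cm < by["B"].cm < 50.0
    assert not conflicts
    kbs = [e.kb for e in entries]
    cms = [e.cm for e in entries]
    assert kbs == sorted(kbs) and cms == sorted(cms)


def test_dual_mapped_loci_keep_linkage_cm():
    frame = _mini_frame()
    fish = [FishAssignment("A", "p2", "p2"), FishAssignment("B", "q2", "q2")]
    linkage = [LinkageEntry("A", 7.0, 7.0), LinkageEntry("B", 44.0, 44.0)]
    entries, conflicts = integrate_chromosome(frame, fish, linkage)
    by = {e.locus: e for e in entries}
    assert by["A"].cm == pytest.approx(7.0)
    assert by["B"].cm == pytest.approx(44.0)
    assert not conflicts


def test_linkage_only_locus_placed_proportionally():
    frame = _mini_frame()
    fish = [FishAssignment("A", "p2", "p2")]
    linkage = [LinkageEntry("A", 5.0, 5.0), LinkageEntry("L", 10.0, 10.0)]
    entries, _ = integrate_chromosome(frame, fish, linkage)
    by = {e.locus: e for e in entries}
    assert by["A"].kb < by["L"].kb < frame.centromere_kb
    assert by["L"].cm == pytest.approx(10.0)
    assert by["L"].source == "linkage"


def test_fish_order_wins_over_conflicting_linkage():
    """A locus whose linkage position contradicts the FISH order is
    reported and re-interpolated instead of reordering the map."""
    frame = _mini_frame()
    fish = [FishAssignment("A", "p2", "p2"), FishAssignment("B", "p1", "p1"),
            FishAssignment("C", "q1", "q1")]
    linkage = [LinkageEntry("A", 5.0, 5.0), LinkageEntry("B", 30.0, 30.0),
               LinkageEntry("C", 25.0, 25.0)]  # C before B contradicts FISH
    entries, conflicts = integrate_chromosome(frame, fish, linkage)
    assert len(conflicts) == 1
    kbs = [e.kb for e in entries]
    cms = [e.cm for e in entries]
    assert kbs == sorted(kbs) and cms == sorted(cms)


def test_breakpoints_receive_interpolated_cm():
    from mapweaver import BreakpointEntry
    frame = _mini_frame()
    frame.breakpoints.append(BreakpointEntry("BREAKPOINT1", 50000.0))
    fish = [FishAssignment("A", "p2", "p2"), FishAssignment("B", "q2", "q2")]
    entries, _ = integrate_chromosome(frame, fish)
    by = {e.locus: e for e in entries}
    assert by["BREAKPOINT1"].cm == pytest.approx(
        interpolate_cm(50000.0, [(by["cen"].kb, by["cen"].cm),
                                 (by["B"].kb, by["B"].cm)]))
    assert by["BREAKPOINT1"].confidence is None


def test_integration_idempotent_on_conflict_free_map():
    frame = _mini_frame()
    fish = [FishAssignment("A", "p2", "p2"), FishAssignment("B", "q1", "q1")]
    linkage = [LinkageEntry("A", 8.0, 8.0)]
    first, _ = integrate_chromosome(frame, fish, linkage)
    second, _ = integrate_chromosome(frame, fish, linkage)
    assert [(e.locus, e.kb, e.cm) for e in first] == \
           [(e.locus, e.kb, e.cm) for e in second]


# ---------------------------------------------------------------------------
# band curation

def _curation_setup(ref_mb_for_B=35.0):
    """A locus B assigned to band p2 but comparatively placed at
    ``ref_mb_for_B`` Mb on a 0-100 Mb forward block covering the whole
    chromosome."""
    frame = _mini_frame()
    fish = [FishAssignment("A", "p2", "p2"), FishAssignment("B", "p2", "p2"),
            FishAssignment("C", "q2", "q2")]
    members = [Marker("A", "c", 0.0, {"MDO": ("M", 10e6)}),
               Marker("B", "c", 0.0, {"MDO": ("M", ref_mb_for_B * 1e6)}),
               Marker("C", "c", 3.0, {"MDO": ("M", 80e6)})]
    block = SyntenyBlock(block_id="b", target_chromosome="c", ref_genome="MDO",
                         ref_chromosome="M", ref_start_bp=0.0, ref_end_bp=100e6,
                         orientation="forward", members=members,
                         target_start_kb=0.0, target_end_kb=100000.0)
    return frame, fish, [block]


def test_consistent_map_converges_in_zero_rounds():
    frame, fish, blocks = _curation_setup(ref_mb_for_B=15.0)
    state = curate_bands(frame, fish, blocks=blocks)
    assert state.curation_round == 0
    assert state.band_edits == []


def test_band_boundary_extended_minimally_to_cover_locus():
    """B sits 15 Mb past the end of its assigned band: the band's q-side
    boundary moves to just past B's position and the tiling is preserved."""
    frame, fish, blocks = _curation_setup(ref_mb_for_B=35.0)
    state = curate_bands(frame, fish, blocks=blocks)
    assert state.curation_round >= 1
    p2 = next(b for b in frame.bands if b.band_id == "p2")
    assert p2.end_kb == pytest.approx(35001.0)  # 35000 kb + 1 kb margin
    from mapweaver.records import validate_band_tiling
    validate_band_tiling(frame.bands, 100.0)


def test_random_boundary_perturbations_converge():
    """Perturbing band boundaries around a consistent map always converges
    back to zero discrepancies within the round cap."""
    rng = np.random.default_rng(13)
    for _ in range(10):
        frame, fish, blocks = _curation_setup(ref_mb_for_B=15.0)
        cut1, cut2 = np.sort(rng.uniform(12, 38, 2))
        frame.bands[0] = BandSpec("p2", cut1, 0.0, cut1)
        frame.bands[1] = BandSpec("p1", cut2 - cut1, cut1, cut2)
        frame.bands[2] = BandSpec("q1", 70.0 - cut2, cut2, 70.0)
        state = curate_bands(frame, fish, blocks=blocks)
        assert state.curation_round <= 20
        for f in fish:
            from mapweaver.integrate import band_union_kb
            lo, hi = band_union_kb(f, frame.bands)
            kb = {e.locus: e.kb for e in state.entries}[f.locus]
            assert lo - 1.0 <= kb <= hi + 1.0


def test_curation_cap_reported_on_unresolvable_conflict():
    """Two co-assigned loci whose comparative order straddles a boundary in
    opposite directions cannot be reconciled: the engine must say so."""
    frame = _mini_frame()
    fish = [FishAssignment("A", "p1", "p1"), FishAssignment("B", "p2", "p2")]
    members = [Marker("A", "c", 0.0, {"MDO": ("M", 10e6)}),
               Marker("B", "c", 0.0, {"MDO": ("M", 30e6)})]
    block = SyntenyBlock(block_id="b", target_chromosome="c", ref_genome="MDO",
                         ref_chromosome="M", ref_start_bp=0.0, ref_end_bp=100e6,
                         orientation="forward", members=members,
                         target_start_kb=0.0, target_end_kb=100000.0)
    with pytest.raises(IntegrationError):
        curate_bands(frame, fish, blocks=[block], max_rounds=5)
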