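"""The synthetic-genome generator and recovery scoring."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mapweaver import (
    BreakpointEntry,
    SimulationConfig,
    TruthTable,
    apply_rearrangements,
    emit_observations,
    score_recovery,
    simulate,
    simulate_reference,
)


def test_reference_is_deterministic_under_seed():
    cfg = SimulationConfig(seed=42)
    a = simulate_reference(cfg, np.random.default_rng(cfg.seed))
    b = simulate_reference(cfg, np.random.default_rng(cfg.seed))
    pd.testing.assert_frame_equal(a, b)


def test_full_simulation_deterministic_under_seed():
    d1 = simulate(SimulationConfig(seed=7))
    d2 = simulate(SimulationConfig(seed=7))
    pd.testing.assert_frame_equal(d1.truth.genes, d2.truth.genes)
    assert d1.truth.breakpoints == d2.truth.breakpoints
    assert {c: [f.locus for f in v] for c, v in d1.fish.items()} == \
           {c: [f.locus for f in v] for c, v in d2.fish.items()}
    assert [(p.chromosome, p.x, p.y) for p in d1.flow_peaks] == \
           [(p.chromosome, p.x, p.y) for p in d2.flow_peaks]


def test_reference_positions_sorted_within_chromosomes():
    cfg = SimulationConfig(seed=1)
    ref = simulate_reference(cfg, np.random.default_rng(1))
    for _, sub in ref.groupby("ref_chromosome"):
        assert sub["ref_bp"].is_monotonic_increasing


def test_intergene_spacing_is_exponential():
    """At n = 10^4 the empirical spacing distribution must pass a KS test
    against the configured exponential."""
    cfg = SimulationConfig(seed=3, n_chromosomes=1, genes_per_chromosome=10_000)
    ref = simulate_reference(cfg, np.random.default_rng(3))
    gaps = np.diff(np.concatenate([[0.0], ref["ref_bp"].values]))
    stat, p = stats.kstest(gaps, "expon",
                           args=(0, cfg.mean_gene_spacing_kb * 1000.0))
    assert p > 0.01


def test_too_few_genes_rejected():
    with pytest.raises(Exception):
        SimulationConfig(genes_per_chromosome=1)


def test_zero_rearrangements_means_no_breakpoints():
    cfg = SimulationConfig(seed=2, n_inversions=0, n_translocations=0)
    rng = np.random.default_rng(2)
    truth = apply_rearrangements(simulate_reference(cfg, rng), cfg, rng)
    assert all(len(v) == 0 for v in truth.breakpoints.values())
    for chrom, sub in truth.genes.groupby("chromosome"):
        assert (sub["ref_chromosome"] == chrom.replace("T", "R")).all()


def test_single_inversion_leaves_two_breakpoints():
    cfg = SimulationConfig(seed=4, n_chromosomes=1, n_inversions=1,
                           n_translocations=0)
    rng = np.random.default_rng(4)
    truth = apply_rearrangements(simulate_reference(cfg, rng), cfg, rng)
    assert len(truth.breakpoints["T1"]) == 2


def test_rearrangements_conserve_gene_content():
    cfg = SimulationConfig(seed=5, n_fusions=1, n_fissions=1)
    rng = np.random.default_rng(5)
    ref = simulate_reference(cfg, rng)
    truth = apply_rearrangements(ref, cfg, rng)
    assert sorted(truth.genes["gene_id"]) == sorted(ref["gene_id"])


def test_fusion_and_fission_change_chromosome_count():
    base = SimulationConfig(seed=6, n_inversions=0, n_translocations=0)
    rng = np.random.default_rng(6)
    fused = apply_rearrangements(
        simulate_reference(base, rng),
        SimulationConfig(seed=6, n_inversions=0, n_translocations=0, n_fusions=1),
        np.random.default_rng(6))
    assert len(fused.size_kb) == base.n_chromosomes - 1
    split = apply_rearrangements(
        simulate_reference(base, np.random.default_rng(6)),
        SimulationConfig(seed=6, n_inversions=0, n_translocations=0, n_fissions=1),
        np.random.default_rng(6))
    assert len(split.size_kb) == base.n_chromosomes + 1


def test_full_fish_single_band_per_arm_assigns_true_arm():
    cfg = SimulationConfig(seed=8, n_chromosomes=1, genes_per_chromosome=100,
                           n_inversions=0, n_translocations=0,
                           fish_fraction=1.0, bands_per_chromosome=2)
    ds = simulate(cfg)
    cen = ds.truth.centromere_kb["T1"]
    kb = ds.truth.genes.set_index("gene_id")["kb"]
    for f in ds.fish["T1"]:
        expected_arm = "p" if kb[f.locus] < cen else "q"
        assert f.band_start.startswith(expected_arm)


def test_noiseless_linkage_preserves_true_order():
    cfg = SimulationConfig(seed=9, linkage_noise_sd=0.0)
    ds = simulate(cfg)
    kb = ds.truth.genes.set_index("gene_id")["kb"]
    for chrom, entries in ds.linkage.items():
        ordered = sorted(entries, key=lambda e: e.cm)
        kbs = [kb[e.locus] for e in ordered]
        assert kbs == sorted(kbs)


def test_realised_leading_gap_matches_configured_m_percent():
    """With a dense gene set, the realised uncovered p-telomeric fraction
    agrees with the configured m% within one percentage point."""
    cfg = SimulationConfig(seed=10, n_chromosomes=1, genes_per_chromosome=10_000,
                           n_inversions=0, n_translocations=0,
                           linkage_fraction=0.5)
    ds = simulate(cfg)
    size = ds.truth.size_kb["T1"]
    kb = ds.truth.genes.set_index("gene_id")["kb"]
    first_marker = min(kb[e.locus] for e in ds.linkage["T1"])
    covered = (1 - cfg.linkage_leading_gap - cfg.linkage_trailing_gap) * size
    realised_m = first_marker / covered * 100.0
    configured_m = ds.coverage["T1"].m_percent
    assert abs(realised_m - configured_m) < 1.0


def test_perfect_inference_scores_perfectly():
    ds = simulate(SimulationConfig(seed=11))
    truth = ds.truth
    bps = {c: [BreakpointEntry(f"b{i}", kb) for i, kb in enumerate(v)]
           for c, v in truth.breakpoints.items()}
    entries = {c: [(r.gene_id, r.kb, 1) for r in sub.itertuples()]
               for c, sub in truth.genes.groupby("chromosome")}
    sizes = dict(truth.size_kb)
    report = score_recovery(bps, entries, sizes, truth, tolerance_kb=1.0)
    assert report.breakpoint_recall == 1.0
    assert report.breakpoint_precision == 1.0
    assert report.spearman_rho == pytest.approx(1.0)
    assert report.mean_abs_error_kb == pytest.approx(0.0)
    assert report.chromosome_accuracy == 1.0


def test_reversed_positions_score_negative_rho():
    ds = simulate(SimulationConfig(seed=12, n_chromosomes=1,
                                   n_inversions=0, n_translocations=0))
    truth = ds.truth
    size = truth.size_kb["T1"]
    entries = {"T1": [(r.gene_id, size - r.kb, 1)
                      for r in truth.genes.itertuples()]}
    report = score_recovery({"T1": []}, entries, {"T1": size}, truth,
                            tolerance_kb=1.0)
    assert report.spearman_rho == pytest.approx(-1.0)


def test_hand_built_case_matches_manual_metrics():
    genes = pd.DataFrame({
        "gene_id": [f"g{i}" for i in range(5)],
        "chromosome": ["T1"] * 5,
        "kb": [10.0, 20.0, 30.0, 40.0, 50.0],
        "ref_chromosome": ["R1"] * 5,
        "ref_bp": [1e4, 2e4, 3e4, 4e4, 5e4],
        "ref_index": range(5),
    })
    truth = TruthTable(genes=genes, breakpoints={"T1": [25.0, 45.0]},
                       blocks={"T1": []}, centromere_kb={"T1": 30.0},
                       size_kb={"T1": 60.0}, size_cm={"T1": 42.0})
    inferred_bp = {"T1": [BreakpointEntry("a", 27.0), BreakpointEntry("b", 10.0)]}
    entries = {"T1": [("g0", 12.0, 2), ("g1", 18.0, 1), ("g2", 30.0, 1)]}
    report = score_recovery(inferred_bp, entries, {"T1": 60.0}, truth,
                            tolerance_kb=3.0)
    # one of two true junctions matched (27 vs 25); 10 matches nothing
    assert report.breakpoint_recall == pytest.approx(0.5)
    assert report.breakpoint_precision == pytest.approx(0.5)
    assert report.mean_abs_error_kb == pytest.approx(2.0)
    assert report.spearman_rho == pytest.approx(1.0)
    assert report.per_confidence_error_kb[2] == pytest.approx(2.0)
    assert report.per_confidence_error_kb[1] == pytest.approx(1.0)


def test_unknown_chromosome_labels_rejected():
    ds = simulate(SimulationConfig(seed=13, n_chromosomes=1,
                                   n_inversions=0, n_translocations=0))
    with pytest.raises(Exception, match="unknown chromosome"):
        score_recovery({}, {"nope": []}, {"nope": 1.0}, ds.truth)
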