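"""End-to-end orchestration: sizes -> synteny -> geometry -> integration ->
virtual map -> scaffold anchoring, one chromosome at a time.

The pipeline is a pure function of its inputs: identical dataset and
options reproduce identical outputs, recorded in a manifest with a config
hash and per-step record counts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

from pydantic import BaseModel

from . import io as mwio
from .errors import IntegrationError, PlacementError
from .flowkaryotype import calibrate, estimate_sizes, genome_size, project_onto_dna_line
from .geometry import arm_sizes, interpolate_bands, place_centromere, \
    place_centromere_within_block
from .integrate import curate_bands, integrate_chromosome, rescale_linkage
from .records import ChromosomeFrame, ChromosomeSpec, MapEntry
from .synteny import Marker, count_blocks, detect_blocks, scale_to_target
from .synthdata import RecoveryReport, SimulationConfig, SyntheticDataset, \
    score_recovery, simulate
from .virtualmap import anchor_scaffolds, build_virtual_map

log = logging.getLogger("mapweaver")


class RunConfig(BaseModel):
    """Options governing a pipeline run (the dataset supplies the inputs)."""

    seed: int = 0
    orphan_window_mb: float = 10.0
    curation_cap: int = 20
    out_dir: str | None = None
    simulation: SimulationConfig | None = None


@dataclass
class ChromosomeResult:
    frame: ChromosomeFrame
    blocks: list
    orphans: list
    breakpoints: list
    integrated: list[MapEntry]
    virtual: list[MapEntry]
    conflicts: list[str]
    curation_rounds: int
    curation_fallback: bool = False


@dataclass
class PipelineResult:
    sizes: dict[str, ChromosomeSpec]
    genome_mb: float
    genome_cm: float
    chromosomes: dict[str, ChromosomeResult] = field(default_factory=dict)
    anchors: list = field(default_factory=list)
    anchor_summary: dict = field(default_factory=dict)
    recovery: RecoveryReport | None = None
    manifest: dict = field(default_factory=dict)


def run_pipeline(dataset: SyntheticDataset, config: RunConfig | None = None) -> PipelineResult:
    """Run every stage on one dataset and score against its truth table."""
    config = config or RunConfig()
    preference = (dataset.config.ref_name, dataset.config.fallback_name)

    # ---- step 1-2: chromosome and genome sizes from flow peaks ----
    anchor = next(p for p in dataset.flow_peaks if p.chromosome == dataset.flow_anchor)
    ref_peaks = [p for p in dataset.flow_peaks if p.species == "reference"]
    tgt_peaks = [p for p in dataset.flow_peaks if p.species == "target"]
    cal = calibrate(project_onto_dna_line(ref_peaks, anchor), dataset.reference_sizes_mb)
    size_cm = {c: dataset.coverage[c].map_length_cm / dataset.coverage_fraction[c]
               for c in dataset.coverage}
    specs = estimate_sizes(project_onto_dna_line(tgt_peaks, anchor), cal, size_cm)
    sizes = {s.name: s for s in specs}
    genome_mb, genome_cm = genome_size(specs)
    log.info("sized %d chromosomes: %.0f Mb / %.2f cM", len(sizes), genome_mb, genome_cm)

    annotation_by_locus = {
        genome: {r.locus: (r.ref_chromosome, r.ref_bp) for r in records}
        for genome, records in dataset.annotation.items()
    }

    # block detection is genome-wide: large reference gaps are resolved by
    # checking whether their content is claimed by blocks elsewhere
    all_markers = []
    for chrom in sorted(sizes):
        all_markers.extend(_build_markers(chrom, dataset, annotation_by_locus))
    blocks_all, orphans_all = detect_blocks(
        all_markers, preference, orphan_window_bp=config.orphan_window_mb * 1e6)

    result = PipelineResult(sizes=sizes, genome_mb=genome_mb, genome_cm=genome_cm)
    vmap_by_chrom: dict[str, list[MapEntry]] = {}
    for chrom in sorted(sizes):
        blocks = [b for b in blocks_all if b.target_chromosome == chrom]
        orphans = [o for o in orphans_all
                   if any(f.locus == o.locus for f in dataset.fish[chrom])]
        cres = _run_chromosome(chrom, sizes[chrom], dataset, annotation_by_locus,
                               preference, config, blocks, orphans)
        result.chromosomes[chrom] = cres
        vmap_by_chrom[chrom] = cres.virtual

    result.anchors, result.anchor_summary = anchor_scaffolds(
        dataset.scaffold_genes, vmap_by_chrom, dataset.scaffold_lengths_bp)

    result.recovery = _score(result, dataset)
    result.manifest = _manifest(result, dataset, config)
    if config.out_dir:
        _write_artifacts(result, config.out_dir)
    return result


def _build_markers(chrom, dataset, annotation_by_locus) -> list[Marker]:
    p_idio, q_idio = dataset.idiograms[chrom]
    band_order = [b.band_id for b in p_idio] + [b.band_id for b in q_idio]
    band_index = {bid: i for i, bid in enumerate(band_order)}
    suborders = dataset.fish_order.get(chrom, {})
    markers = []
    for f in dataset.fish[chrom]:
        orth = {}
        for genome, table in annotation_by_locus.items():
            if f.locus in table:
                orth[genome] = table[f.locus]
        resolved = f.locus in suborders
        order = suborders.get(
            f.locus, 0.5 * (band_index[f.band_start] + band_index[f.band_end] + 1.0))
        markers.append(Marker(locus=f.locus, chromosome=chrom, fish_order=order,
                              orthologues=orth, band=f.band_start,
                              order_resolved=resolved))
    return markers


def _run_chromosome(chrom, spec, dataset, annotation_by_locus, preference, config,
                    blocks, orphans):
    fish = dataset.fish[chrom]
    linkage = dataset.linkage.get(chrom)
    coverage = dataset.coverage.get(chrom)
    p_idio, q_idio = dataset.idiograms[chrom]

    # ---- step 3: breakpoints from genome-wide blocks ----
    blocks, breakpoints = scale_to_target(blocks, spec.size_mb)
    log.info("%s: %d blocks, %d breakpoints, %d orphans",
             chrom, len(blocks), len(breakpoints), len(orphans))

    # ---- step 4: centromere and arms ----
    p_bands = {b.band_id for b in p_idio}
    p_loci = {f.locus for f in fish if f.band_start in p_bands}
    q_loci = {f.locus for f in fish if f.band_start not in p_bands}
    cen_ref_bp = None
    cen_genome = None
    try:
        cen_kb = place_centromere(blocks, p_loci, q_loci)
    except PlacementError:
        cen_kb, cen_ref_bp, cen_genome = _centromere_within(blocks, p_loci, q_loci)
    cen_kb = min(max(cen_kb, 1.0), spec.size_kb - 1.0)

    arms = arm_sizes(spec, cen_kb)
    arms, cen_kb = _adjust_arms_to_flanks(spec, cen_kb, arms, dataset, chrom, blocks)
    bands = interpolate_bands(p_idio, q_idio, arms)
    frame = ChromosomeFrame(spec=spec, arms=arms, bands=bands,
                            centromere_kb=cen_kb, breakpoints=breakpoints)

    # ---- steps 6-7: integration with band curation ----
    fallback = False
    try:
        state = curate_bands(frame, fish, linkage, coverage, blocks,
                             max_rounds=config.curation_cap)
        integrated, conflicts, rounds = state.entries, state.conflicts, state.curation_round
    except IntegrationError as exc:
        log.warning("%s: band curation unresolved (%s); using band-clamped map", chrom, exc)
        integrated, conflicts = integrate_chromosome(frame, fish, linkage, coverage,
                                                     blocks, clamp_to_band=True)
        rounds, fallback = config.curation_cap, True

    # ---- step 8: virtual map ----
    ref_bp_by_genome = {
        genome: {loc: pos[1] for loc, pos in table.items()}
        for genome, table in annotation_by_locus.items()
    }
    if cen_ref_bp is not None:
        ref_bp_by_genome.setdefault(cen_genome, {})["cen"] = cen_ref_bp
    virtual, warnings = build_virtual_map(frame, integrated, blocks, dataset.annotation,
                                          ref_bp_by_genome, preference=preference)
    for w in warnings:
        log.debug("%s: %s", chrom, w)
    return ChromosomeResult(frame=frame, blocks=blocks, orphans=orphans,
                            breakpoints=breakpoints, integrated=integrated,
                            virtual=virtual, conflicts=conflicts,
                            curation_rounds=rounds, curation_fallback=fallback)


def _centromere_within(blocks, p_loci, q_loci):
    """p/q transition inside one block: reference midpoint of the flanking
    markers, rescaled onto the block's target extent."""
    for b in blocks:
        member_p = [m for m in b.members if m.locus in p_loci]
        member_q = [m for m in b.members if m.locus in q_loci]
        if member_p and member_q:
            flank_left, flank_right = member_p[-1], member_q[0]
            kb = place_centromere_within_block(b, flank_left, flank_right)
            mid_bp = 0.5 * (flank_left.coord(b.ref_genome)[1]
                            + flank_right.coord(b.ref_genome)[1])
            return kb, mid_bp, b.ref_genome
    raise PlacementError("no block contains FISH markers from both arms")


def _adjust_arms_to_flanks(spec, cen_kb, arms, dataset, chrom, blocks):
    """Minimally shift the arm cM boundary so the centromere cM lies between
    the nearest dual-mapped (FISH + linkage) markers on either side."""
    linkage = dataset.linkage.get(chrom)
    coverage = dataset.coverage.get(chrom)
    if not linkage or not coverage:
        return arms, cen_kb
    anchored = {e.locus: e.cm for e in rescale_linkage(linkage, coverage, spec.size_cm)}
    placed = {}
    for b in blocks:
        if b.target_start_kb is None:
            continue
        for m in b.members:
            if m.locus in anchored:
                from .geometry import ref_to_target_kb
                placed[m.locus] = ref_to_target_kb(b, m.coord(b.ref_genome)[1])
    p_cms = [anchored[l] for l, kb in placed.items() if kb < cen_kb]
    q_cms = [anchored[l] for l, kb in placed.items() if kb > cen_kb]
    if not p_cms or not q_cms:
        return arms, cen_kb
    p_flank, q_flank = max(p_cms), min(q_cms)
    if p_flank >= q_flank:
        return arms, cen_kb  # contradictory linkage; leave proportional arms
    return arm_sizes(spec, cen_kb, p_flank, q_flank), cen_kb


def _score(result: PipelineResult, dataset: SyntheticDataset) -> RecoveryReport:
    truth_genes = set(dataset.truth.genes["gene_id"])
    entries = {}
    orientations = {}
    for chrom, cres in result.chromosomes.items():
        entries[chrom] = [(e.locus, e.kb, e.confidence) for e in cres.virtual
                          if e.locus in truth_genes]
        orientations[chrom] = [(b.target_start_kb, b.target_end_kb, b.orientation)
                               for b in cres.blocks if not b.is_gap]
    sizes_kb = {c: s.size_kb for c, s in result.sizes.items()}
    n_fish = sum(len(v) for v in dataset.fish.values())
    tolerance = sum(sizes_kb.values()) / (n_fish + len(sizes_kb))
    return score_recovery(
        {c: result.chromosomes[c].breakpoints for c in result.chromosomes},
        entries, sizes_kb, dataset.truth, tolerance_kb=tolerance,
        inferred_orientations=orientations,
    )


def _manifest(result: PipelineResult, dataset: SyntheticDataset, config: RunConfig) -> dict:
    cfg = {"run": config.model_dump(), "simulation": dataset.config.model_dump()}
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    counts = {
        chrom: {
            "blocks": len(c.blocks),
            "breakpoints": len(c.breakpoints),
            "orphans": len(c.orphans),
            "integrated_entries": len(c.integrated),
            "virtual_entries": len(c.virtual),
            "conflicts": len(c.conflicts),
            "curation_rounds": c.curation_rounds,
            "curation_fallback": c.curation_fallback,
        }
        for chrom, c in result.chromosomes.items()
    }
    return {
        "config_hash": hashlib.sha256(blob).hexdigest(),
        "genome_mb": result.genome_mb,
        "genome_cm": result.genome_cm,
        "chromosomes": counts,
        "anchor_summary": result.anchor_summary,
    }


def _write_artifacts(result: PipelineResult, out_dir: str) -> None:
    os.makedirs(out_dir, exist_ok=True)
    for chrom, cres in result.chromosomes.items():
        mwio.write_map(cres.integrated, os.path.join(out_dir, f"{chrom}.integrated.tsv"))
        mwio.write_map(cres.virtual, os.path.join(out_dir, f"{chrom}.virtual.tsv"))
        mwio.write_input_file(cres.breakpoints, "breakpoints",
                              os.path.join(out_dir, f"{chrom}.breakpoints.tsv"))
        mwio.write_input_file(cres.frame.arms, "arm",
                              os.path.join(out_dir, f"{chrom}.arms.tsv"))
        mwio.write_input_file(cres.frame.bands, "band",
                              os.path.join(out_dir, f"{chrom}.bands.tsv"))
    report = result.manifest.copy()
    if result.recovery is not None:
        report["recovery"] = dataclasses.asdict(result.recovery)
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)


def run_synthetic(sim_config: SimulationConfig | None = None,
                  run_config: RunConfig | None = None) -> tuple[PipelineResult, SyntheticDataset]:
    """Simulate a dataset under the default (or given) study conditions and
    run the full pipeline on it."""
    run_config = run_config or RunConfig()
    sim_config = sim_config or run_config.simulation or SimulationConfig(seed=run_config.seed)
    dataset = simulate(sim_config)
    return run_pipeline(dataset, run_config), dataset


def block_count_summary(result: PipelineResult):
    """Per-chromosome block counts, total and mean, from the inferred
    breakpoints."""
    return count_blocks({c: r.breakpoints for c, r in result.chromosomes.items()})
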