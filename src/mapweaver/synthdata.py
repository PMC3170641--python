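"""Synthetic genomes with known truth for exercising the whole pipeline.

A reference genome of gene positions is simulated, a target genome is
derived from it by known rearrangements (inversions, translocations,
fusions, fissions), and the observable inputs the pipeline consumes are
emitted from the target with realistic degradation: band-resolution FISH
assignments for a subset of genes, a partial-coverage noisy linkage map
(the uncovered p-telomeric fraction defines m%), per-gene reference
orthologue coordinates, flow-karyotype peaks with multiplicative noise, and
gene-scaffold memberships.  Every quantity the pipeline infers can then be
scored against the recorded truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy import stats

from .errors import ValidationError
from .records import (
    BreakpointEntry,
    FishAssignment,
    LinkageCoverage,
    LinkageEntry,
    OrthologueRecord,
)
from .flowkaryotype import FlowPeak
from .geometry import IdiogramBand
from . import reference_data


class SimulationConfig(BaseModel):
    """Study conditions for the synthetic genome.

    Defaults model the scale of the real datasets the pipeline was designed
    for: a marsupial-sized genome of 7 autosomes, FISH on ~20% of genes at
    whole-band resolution, a sparse linkage map covering the middle of each
    chromosome, and ~1% flow-cytometry peak noise.
    """

    seed: int = 0
    n_chromosomes: int = 7
    genes_per_chromosome: int = 300
    n_inversions: int = 9
    n_translocations: int = 6
    n_fusions: int = 0
    n_fissions: int = 0
    fish_fraction: float = Field(0.2, ge=0.0, le=1.0)
    bands_per_chromosome: int = 8
    linkage_fraction: float = Field(0.06, ge=0.0, le=1.0)
    linkage_leading_gap: float = Field(0.08, ge=0.0, lt=1.0)  # p-telomeric, defines m%
    linkage_trailing_gap: float = Field(0.02, ge=0.0, lt=1.0)
    linkage_noise_sd: float = 1.0  # cM
    flow_noise_cv: float = 0.01
    mean_gene_spacing_kb: float = 1000.0
    cm_per_mb: float = 0.7
    ref_name: str = "REF"
    fallback_name: str = "ALT"

    @model_validator(mode="after")
    def _check(self):
        if self.genes_per_chromosome < 2:
            raise ValueError("genes_per_chromosome must be >= 2")
        if self.linkage_leading_gap + self.linkage_trailing_gap >= 1:
            raise ValueError("linkage gaps must leave a covered interval")
        return self

    @property
    def n_rearrangements(self) -> int:
        return self.n_inversions + self.n_translocations + self.n_fusions + self.n_fissions


@dataclass
class TruthTable:
    """Ground truth of the simulated target genome."""

    genes: pd.DataFrame  # gene_id, chromosome, kb, ref_chromosome, ref_bp, ref_index
    breakpoints: dict[str, list[float]]  # chrom -> junction kb, sorted
    blocks: dict[str, list[dict]]  # chrom -> [{start_kb,end_kb,ref_chromosome,orientation}]
    centromere_kb: dict[str, float]
    size_kb: dict[str, float]
    size_cm: dict[str, float]


@dataclass
class SyntheticDataset:
    """Everything the pipeline consumes, plus the truth to score against."""

    config: SimulationConfig
    truth: TruthTable
    annotation: dict[str, list[OrthologueRecord]]
    idiograms: dict[str, tuple[list[IdiogramBand], list[IdiogramBand]]]
    fish: dict[str, list[FishAssignment]]
    linkage: dict[str, list[LinkageEntry]]
    coverage: dict[str, LinkageCoverage]
    coverage_fraction: dict[str, float]  # covered cM / full cM, an observed input
    # cytogenetic order index per FISH locus: integer part = band index;
    # breakpoint-flanking probes carry a FISH-resolved sub-band order,
    # fill-in probes sit unordered at band + 0.5
    fish_order: dict[str, dict[str, float]] = field(default_factory=dict)
    flow_peaks: list[FlowPeak] = field(default_factory=list)
    reference_sizes_mb: dict[str, float] = field(default_factory=dict)
    flow_anchor: str = "HSA4"
    scaffold_genes: dict[str, list[str]] = field(default_factory=dict)
    scaffold_lengths_bp: dict[str, int] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# reference genome


def simulate_reference(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Gene positions on the reference genome: exponential inter-gene
    spacings (mean = mean_gene_spacing_kb) per reference chromosome."""
    if config.genes_per_chromosome < 2:
        raise ValidationError("genes_per_chromosome must be >= 2")
    rows = []
    for c in range(config.n_chromosomes):
        chrom = f"R{c + 1}"
        gaps = rng.exponential(config.mean_gene_spacing_kb * 1000.0,
                               config.genes_per_chromosome)
        pos = np.cumsum(gaps)
        for i, bp in enumerate(pos):
            rows.append((f"g{c + 1:02d}_{i:04d}", chrom, float(bp), i))
    return pd.DataFrame(rows, columns=["gene_id", "ref_chromosome", "ref_bp", "ref_index"])


# ---------------------------------------------------------------------------
# rearrangement


def apply_rearrangements(reference: pd.DataFrame, config: SimulationConfig,
                         rng: np.random.Generator) -> TruthTable:
    """Derive the target genome by applying the configured rearrangements.

    Gene content is conserved exactly; every junction between genes that are
    not reference-adjacent is recorded as a true breakpoint.
    """
    gene_info = reference.set_index("gene_id")
    chroms: dict[str, list[str]] = {}
    for c, sub in reference.groupby("ref_chromosome"):
        chroms[c.replace("R", "T")] = list(sub.sort_values("ref_bp")["gene_id"])

    ops = (["inversion"] * config.n_inversions
           + ["translocation"] * config.n_translocations
           + ["fusion"] * config.n_fusions
           + ["fission"] * config.n_fissions)
    rng.shuffle(ops)
    # segment ops act on disjoint intervals: breakpoint reuse is the
    # exception in chromosome evolution, and the conserved segments the
    # method assumes are large and cleanly separated
    claimed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    skipped = []
    for op in ops:
        if not _apply_op(op, chroms, rng, claimed):
            skipped.append(op)

    mean_bp = config.mean_gene_spacing_kb * 1000.0
    rows = []
    breakpoints: dict[str, list[float]] = {}
    blocks: dict[str, list[dict]] = {}
    size_kb: dict[str, float] = {}
    for chrom in sorted(chroms, key=_chrom_sort_key):
        genes = chroms[chrom]
        kb_positions, junctions, blks = _layout(genes, gene_info, mean_bp)
        for g, kb in zip(genes, kb_positions):
            info = gene_info.loc[g]
            rows.append((g, chrom, kb, info["ref_chromosome"], info["ref_bp"],
                         int(info["ref_index"])))
        breakpoints[chrom] = junctions
        blocks[chrom] = blks
        size_kb[chrom] = kb_positions[-1] + mean_bp / 1000.0
    genes_df = pd.DataFrame(
        rows, columns=["gene_id", "chromosome", "kb", "ref_chromosome", "ref_bp", "ref_index"]
    )
    centromere = {}
    for chrom, junctions in breakpoints.items():
        target = size_kb[chrom] * rng.uniform(0.35, 0.55)
        candidates = [j for j in junctions
                      if 0.2 * size_kb[chrom] < j < 0.8 * size_kb[chrom]]
        centromere[chrom] = (min(candidates, key=lambda j: abs(j - target))
                             if candidates else target)
    size_cm = {c: size_kb[c] / 1000.0 * config.cm_per_mb for c in size_kb}
    return TruthTable(genes=genes_df, breakpoints=breakpoints, blocks=blocks,
                      centromere_kb=centromere, size_kb=size_kb, size_cm=size_cm)


def _chrom_sort_key(name: str):
    digits = "".join(ch for ch in name if ch.isdigit())
    return (int(digits) if digits else 0, name)


def _apply_op(op: str, chroms: dict[str, list[str]], rng: np.random.Generator,
              claimed: dict[str, list[tuple[int, int]]] | None = None) -> bool:
    names = sorted(chroms, key=_chrom_sort_key)
    sizes = np.array([len(chroms[n]) for n in names], dtype=float)
    claimed = claimed if claimed is not None else {n: [] for n in names}
    if op == "fusion":
        if len(names) < 2:
            return False
        a, b = rng.choice(len(names), size=2, replace=False)
        claimed.setdefault(names[a], [])
        chroms[names[a]] = chroms[names[a]] + chroms.pop(names[b])
        claimed.pop(names[b], None)
        return True
    if op == "fission":
        eligible = [n for n in names if len(chroms[n]) >= 4]
        if not eligible:
            return False
        n = eligible[rng.integers(len(eligible))]
        cut = int(rng.integers(2, len(chroms[n]) - 1))
        new_name = f"T{max(_chrom_sort_key(x)[0] for x in chroms) + 1}"
        chroms[new_name] = chroms[n][cut:]
        chroms[n] = chroms[n][:cut]
        claimed[new_name] = []
        return True
    # segment operations on disjoint, previously untouched intervals
    weights = sizes / sizes.sum()
    for _ in range(40):  # rejection sampling against claimed intervals
        src = names[rng.choice(len(names), p=weights)]
        genes = chroms[src]
        n = len(genes)
        if n < 6:
            continue
        if op == "inversion":
            # chromosome-scale inversions, the visible kind at band resolution
            length = int(rng.integers(max(2, int(0.2 * n)), max(3, int(0.45 * n))))
        else:
            length = int(rng.integers(max(2, int(0.1 * n)), max(3, int(0.25 * n))))
        start = int(rng.integers(0, n - length))
        span = (start, start + length)
        if any(span[0] < hi and lo < span[1] for lo, hi in claimed.get(src, [])):
            continue
        if op == "inversion":
            genes[start:start + length] = genes[start:start + length][::-1]
            claimed.setdefault(src, []).append(span)
            return True
        # translocation
        others = [x for x in names if x != src]
        if not others:
            return False
        dst = others[rng.integers(len(others))]
        segment = genes[start:start + length]
        at = None
        for _ in range(40):
            cand = int(rng.integers(0, len(chroms[dst]) + 1))
            if not any(lo < cand < hi for lo, hi in claimed.get(dst, [])):
                at = cand
                break
        if at is None:
            continue
        chroms[src] = genes[:start] + genes[start + length:]
        claimed[src] = [(lo - length if lo >= span[1] else lo,
                         hi - length if hi > span[1] else hi)
                        for lo, hi in claimed.get(src, []) if hi <= span[0] or lo >= span[1]]
        chroms[dst] = chroms[dst][:at] + segment + chroms[dst][at:]
        claimed[dst] = [(lo + length if lo >= at else lo,
                         hi + length if hi > at else hi)
                        for lo, hi in claimed.get(dst, [])]
        claimed[dst].append((at, at + length))
        return True
    return False


def _layout(genes: list[str], gene_info: pd.DataFrame, mean_bp: float
            ) -> tuple[list[float], list[float], list[dict]]:
    """Target kb positions preserving reference spacing within ref-adjacent
    runs; the mean spacing is inserted at every junction."""
    kb: list[float] = [mean_bp / 1000.0]
    junctions: list[float] = []
    block_start_idx = [0]
    for i in range(1, len(genes)):
        a = gene_info.loc[genes[i - 1]]
        b = gene_info.loc[genes[i]]
        adjacent = (a["ref_chromosome"] == b["ref_chromosome"]
                    and abs(int(a["ref_index"]) - int(b["ref_index"])) == 1)
        gap_kb = (abs(b["ref_bp"] - a["ref_bp"]) if adjacent else mean_bp) / 1000.0
        kb.append(kb[-1] + gap_kb)
        if not adjacent:
            junctions.append(0.5 * (kb[-2] + kb[-1]))
            block_start_idx.append(i)
    blocks = []
    bounds = block_start_idx + [len(genes)]
    for s, e in zip(bounds, bounds[1:]):
        seg = [gene_info.loc[g] for g in genes[s:e]]
        if len(seg) >= 2:
            orientation = "forward" if seg[-1]["ref_bp"] > seg[0]["ref_bp"] else "reverse"
        else:
            orientation = "unknown"
        blocks.append({
            "start_kb": kb[s] if s == 0 else junctions[block_start_idx.index(s) - 1],
            "end_kb": kb[e - 1],
            "ref_chromosome": seg[0]["ref_chromosome"],
            "orientation": orientation,
            "genes": genes[s:e],
        })
    return kb, junctions, blocks


# ---------------------------------------------------------------------------
# observations


def emit_observations(truth: TruthTable, config: SimulationConfig,
                      rng: np.random.Generator) -> SyntheticDataset:
    """Generate the pipeline's observable inputs from the truth genome."""
    if truth.genes.empty:
        raise ValidationError("empty truth table")
    annotation = {config.ref_name: [
        OrthologueRecord(locus=r.gene_id, ref_bp=float(r.ref_bp),
                         ref_chromosome=str(r.ref_chromosome))
        for r in truth.genes.itertuples()
    ]}
    idiograms: dict[str, tuple[list[IdiogramBand], list[IdiogramBand]]] = {}
    fish: dict[str, list[FishAssignment]] = {}
    fish_order: dict[str, dict[str, float]] = {}
    linkage: dict[str, list[LinkageEntry]] = {}
    coverage: dict[str, LinkageCoverage] = {}
    coverage_fraction: dict[str, float] = {}

    for chrom, sub in truth.genes.groupby("chromosome"):
        sub = sub.sort_values("kb")
        size = truth.size_kb[chrom]
        cen = truth.centromere_kb[chrom]
        p_frac = cen / size
        idiograms[chrom] = _make_idiogram(config.bands_per_chromosome, p_frac, rng)
        band_edges = _true_band_edges(idiograms[chrom], cen, size)

        # FISH targets breakpoint-flanking genes (each block's terminal genes,
        # as the real probe-selection strategy did), then uniform fill-in
        n_fish = max(2, round(config.fish_fraction * len(sub)))
        end_genes = set()
        for blk in truth.blocks[chrom]:
            end_genes.update((blk["genes"][0], blk["genes"][-1]))
        idx_of = {g: i for i, g in enumerate(sub["gene_id"])}
        chosen = {idx_of[g] for g in end_genes}
        remaining = [i for i in range(len(sub)) if i not in chosen]
        n_fill = max(0, n_fish - len(chosen))
        if n_fill and remaining:
            fill = rng.choice(len(remaining), size=min(n_fill, len(remaining)),
                              replace=False)
            chosen.update(remaining[int(i)] for i in fill)
        fish[chrom] = []
        band_idx = {bid: k for k, (bid, _, _) in enumerate(band_edges)}
        per_band_ends: dict[str, list[tuple[float, str]]] = {}
        assignments = []
        for i in sorted(chosen):
            row = sub.iloc[int(i)]
            band = _band_at(band_edges, row["kb"])
            assignments.append((row["gene_id"], band, float(row["kb"])))
            if row["gene_id"] in end_genes:
                per_band_ends.setdefault(band, []).append((float(row["kb"]),
                                                           row["gene_id"]))
        # dual-colour FISH of co-hybridised breakpoint-flanking probes
        # resolves their order within a band; fill-in probes stay unordered
        suborder: dict[str, float] = {}
        for band, ends in per_band_ends.items():
            ends.sort()
            for r, (_, gid) in enumerate(ends):
                frac = (r + 1) / (len(ends) + 1)
                if abs(frac - 0.5) < 1e-9:
                    frac = 0.54  # keep resolved probes distinct from unordered ones
                suborder[gid] = frac
        fish_order[chrom] = {}
        for gid, band, kb in assignments:
            fish[chrom].append(FishAssignment(gid, band, band))
            if gid in suborder:
                fish_order[chrom][gid] = band_idx[band] + suborder[gid]

        cov_start = config.linkage_leading_gap * size
        cov_end = (1 - config.linkage_trailing_gap) * size
        covered = sub[(sub["kb"] >= cov_start) & (sub["kb"] <= cov_end)]
        n_link = max(2, round(config.linkage_fraction * len(sub)))
        pick = np.sort(rng.choice(len(covered), size=min(n_link, len(covered)),
                                  replace=False))
        map_length = (cov_end - cov_start) / 1000.0 * config.cm_per_mb
        entries = []
        for i in pick:
            row = covered.iloc[int(i)]
            cm = (row["kb"] - cov_start) / 1000.0 * config.cm_per_mb
            cm = float(np.clip(cm + rng.normal(0.0, config.linkage_noise_sd),
                               0.0, map_length))
            entries.append(LinkageEntry(row["gene_id"], cm, cm))
        linkage[chrom] = entries
        m_percent = cov_start / (cov_end - cov_start) * 100.0
        coverage[chrom] = LinkageCoverage(chrom, map_length, m_percent)
        coverage_fraction[chrom] = (cov_end - cov_start) / size

    peaks, ref_sizes = _flow_peaks(truth, config, rng)
    scaffold_genes, scaffold_lengths = _make_scaffolds(truth, config, rng)
    return SyntheticDataset(
        config=config, truth=truth, annotation=annotation, idiograms=idiograms,
        fish=fish, fish_order=fish_order, linkage=linkage, coverage=coverage,
        coverage_fraction=coverage_fraction, flow_peaks=peaks,
        reference_sizes_mb=ref_sizes, flow_anchor="HSA4",
        scaffold_genes=scaffold_genes, scaffold_lengths_bp=scaffold_lengths,
    )


def _make_idiogram(n_bands: int, p_frac: float, rng: np.random.Generator):
    """Split the band count between arms by arm size and draw band widths
    from a Dirichlet with moderate concentration — cytogenetic bands are
    unequal but of the same visual magnitude (a synthetic convention)."""
    n_p = int(np.clip(round(n_bands * p_frac), 1, n_bands - 1))
    n_q = n_bands - n_p
    p_bands, q_bands = [], []
    widths = rng.dirichlet([6.0] * n_p)
    edges = np.concatenate([[0.0], np.cumsum(widths)])
    edges[-1] = 1.0
    for i in range(n_p):
        # p bands are numbered outward from the centromere: p{n_p} at ptr
        p_bands.append(IdiogramBand(f"p{n_p - i}", float(edges[i]), float(edges[i + 1])))
    widths = rng.dirichlet([6.0] * n_q)
    edges = np.concatenate([[0.0], np.cumsum(widths)])
    edges[-1] = 1.0
    for i in range(n_q):
        q_bands.append(IdiogramBand(f"q{i + 1}", float(edges[i]), float(edges[i + 1])))
    return p_bands, q_bands


def _true_band_edges(idiogram, cen_kb: float, size_kb: float) -> list[tuple[str, float, float]]:
    p_bands, q_bands = idiogram
    edges = []
    for b in p_bands:
        edges.append((b.band_id, b.start_fraction * cen_kb, b.end_fraction * cen_kb))
    q_len = size_kb - cen_kb
    for b in q_bands:
        edges.append((b.band_id, cen_kb + b.start_fraction * q_len,
                      cen_kb + b.end_fraction * q_len))
    return edges


def _band_at(edges, kb: float) -> str:
    for band_id, lo, hi in edges:
        if lo <= kb < hi:
            return band_id
    return edges[-1][0]


def _flow_peaks(truth: TruthTable, config: SimulationConfig, rng: np.random.Generator):
    """Bivariate peaks on a DNA-line with multiplicative distance noise.

    The generating size model is size = conversion x distance + offset with
    conversion 2.0 Mb/unit and offset 8.0 Mb; human reference chromosome
    sizes provide the calibration points.
    """
    conversion, offset = 2.0, 8.0
    theta = np.deg2rad(40.0)
    u = np.array([np.cos(theta), np.sin(theta)])
    perp = np.array([-u[1], u[0]])
    ref_sizes = reference_data.human_chromosome_sizes()
    peaks = []
    for name, size_mb in ref_sizes.items():
        d = (size_mb - offset) / conversion * (1 + config.flow_noise_cv * rng.normal())
        xy = d * u + rng.normal(0.0, 0.2) * perp
        peaks.append(FlowPeak(name, "reference", max(xy[0], 0.0), max(xy[1], 0.0)))
    for chrom, size_kb in truth.size_kb.items():
        d = (size_kb / 1000.0 - offset) / conversion * (1 + config.flow_noise_cv * rng.normal())
        xy = d * u + rng.normal(0.0, 0.2) * perp
        peaks.append(FlowPeak(chrom, "target", max(xy[0], 0.0), max(xy[1], 0.0)))
    return peaks, ref_sizes


def _make_scaffolds(truth: TruthTable, config: SimulationConfig, rng: np.random.Generator):
    """Tile consecutive truth genes into scaffolds of 1-4 genes."""
    scaffold_genes: dict[str, list[str]] = {}
    lengths: dict[str, int] = {}
    sid = 0
    for chrom, sub in truth.genes.groupby("chromosome"):
        sub = sub.sort_values("kb")
        i = 0
        while i < len(sub):
            k = int(rng.integers(1, 5))
            rows = sub.iloc[i:i + k]
            name = f"scf{sid:05d}"
            scaffold_genes[name] = list(rows["gene_id"])
            span_kb = float(rows["kb"].max() - rows["kb"].min())
            lengths[name] = int(span_kb * 1000) + int(config.mean_gene_spacing_kb * 1000)
            sid += 1
            i += k
    return scaffold_genes, lengths


def simulate(config: SimulationConfig) -> SyntheticDataset:
    """One-call generator: reference -> rearranged truth -> observations,
    fully determined by config.seed."""
    rng = np.random.default_rng(config.seed)
    reference = simulate_reference(config, rng)
    truth = apply_rearrangements(reference, config, rng)
    return emit_observations(truth, config, rng)


# ---------------------------------------------------------------------------
# scoring


@dataclass
class RecoveryReport:
    breakpoint_recall: float
    breakpoint_precision: float
    mean_abs_error_kb: float
    spearman_rho: float
    orientation_accuracy: float
    per_confidence_error_kb: dict[int, float]
    chromosome_accuracy: float
    n_breakpoints_true: int
    n_breakpoints_inferred: int
    n_genes_scored: int


def score_recovery(
    inferred_breakpoints: dict[str, list[BreakpointEntry]],
    inferred_entries: dict[str, list],
    inferred_sizes_kb: dict[str, float],
    truth: TruthTable,
    tolerance_kb: float | None = None,
    inferred_orientations: dict[str, list[tuple[float, float, str]]] | None = None,
) -> RecoveryReport:
    """Score inferred maps against the truth genome.

    ``inferred_entries``: chrom -> list of (gene_id, kb, confidence).
    Inferred positions are rescaled by true/inferred chromosome size before
    positional comparison, since the two coordinate systems differ by the
    flow-karyotype size estimate.  Default tolerance = mean true inter-gene
    gap of the FISH-resolution marker set is the caller's job; here the
    default is the mean inter-breakpoint spacing / 10 fallback.
    """
    unknown = set(inferred_entries) - set(truth.size_kb)
    if unknown:
        raise ValidationError(f"unknown chromosome labels in inferred maps: {unknown}")
    gene_truth = truth.genes.set_index("gene_id")

    if tolerance_kb is None:
        gaps = [truth.size_kb[c] / max(1, len(truth.breakpoints[c]) + 1)
                for c in truth.size_kb]
        tolerance_kb = float(np.mean(gaps)) / 10.0

    tp = 0
    abs_errors = []
    n_true = sum(len(v) for v in truth.breakpoints.values())
    n_inf = 0
    for chrom, bps in inferred_breakpoints.items():
        scale = truth.size_kb[chrom] / inferred_sizes_kb[chrom]
        inf_kb = sorted(b.kb * scale for b in bps)
        n_inf += len(inf_kb)
        used = set()
        for t in truth.breakpoints[chrom]:
            best, best_d = None, None
            for i, x in enumerate(inf_kb):
                if i in used:
                    continue
                d = abs(x - t)
                if best_d is None or d < best_d:
                    best, best_d = i, d
            if best is not None and best_d <= tolerance_kb:
                used.add(best)
                tp += 1
                abs_errors.append(best_d)

    rhos = []
    per_conf: dict[int, list[float]] = {}
    n_scored = 0
    n_correct_chrom = 0
    n_total_genes = 0
    for chrom, entries in inferred_entries.items():
        scale = truth.size_kb[chrom] / inferred_sizes_kb[chrom]
        t_kb, i_kb = [], []
        for gene_id, kb, conf in entries:
            if gene_id not in gene_truth.index:
                continue
            row = gene_truth.loc[gene_id]
            n_total_genes += 1
            if row["chromosome"] != chrom:
                continue
            n_correct_chrom += 1
            t_kb.append(float(row["kb"]))
            i_kb.append(kb * scale)
            if conf is not None:
                per_conf.setdefault(int(conf), []).append(abs(kb * scale - float(row["kb"])))
        if len(t_kb) >= 3:
            rho = stats.spearmanr(t_kb, i_kb).statistic
            rhos.append(float(rho))
        n_scored += len(t_kb)

    orient_hits, orient_total = 0, 0
    if inferred_orientations:
        for chrom, items in inferred_orientations.items():
            scale = truth.size_kb[chrom] / inferred_sizes_kb[chrom]
            for start_kb, end_kb, orientation in items:
                if orientation == "unknown":
                    continue
                mid = 0.5 * (start_kb + end_kb) * scale
                blk = _truth_block_at(truth.blocks.get(chrom, []), mid)
                if blk is None or blk["orientation"] == "unknown":
                    continue
                orient_total += 1
                if blk["orientation"] == orientation:
                    orient_hits += 1

    return RecoveryReport(
        breakpoint_recall=tp / n_true if n_true else 1.0,
        breakpoint_precision=tp / n_inf if n_inf else 1.0,
        mean_abs_error_kb=float(np.mean(abs_errors)) if abs_errors else 0.0,
        spearman_rho=float(np.mean(rhos)) if rhos else 1.0,
        orientation_accuracy=orient_hits / orient_total if orient_total else 1.0,
        per_confidence_error_kb={k: float(np.mean(v)) for k, v in sorted(per_conf.items())},
        chromosome_accuracy=n_correct_chrom / n_total_genes if n_total_genes else 1.0,
        n_breakpoints_true=n_true,
        n_breakpoints_inferred=n_inf,
        n_genes_scored=n_scored,
    )


def _truth_block_at(blocks: list[dict], kb: float) -> dict | None:
    for b in blocks:
        if b["start_kb"] - 1e-6 <= kb <= b["end_kb"] + 1e-6:
            return b
    return None
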