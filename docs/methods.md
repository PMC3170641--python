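# Methods

This note documents the models and procedures implemented in `mapweaver`,
the parameters that matter, the design choices made where the method
description left the design open, and what the synthetic study does and
does not demonstrate.

## Coordinate model

Each chromosome has one physical axis (kb from the p-telomere, `ptr` = 0,
`qtr` = chromosome size) and one genetic axis (cM, `ptr` = 0, `qtr` = the
full-coverage linkage length).  Cytogenetic bands are half-open kb
intervals tiling the chromosome.  All reference-genome coordinates are bp.
kb values are rounded to integers and cM to two decimals at serialisation
only; full precision is kept internally.  The epsilon for "strictly
between" decisions is 1 kb / 0.01 cM.

## Flow-karyotype sizing

Peak positions in (Hoechst, chromomycin) space are projected onto the ray
from the origin through the anchor chromosome's peak (human chromosome 4);
the scalar projection estimates DNA content.  Sizes are fitted by ordinary
least squares over all reference chromosomes, `size = conversion × distance
+ offset`; the anchor defines the line but carries no special weight in the
fit.  Target sizes are reported to integer Mb.  Under multiplicative peak
noise of 1% the conversion is recovered well within 5%, and per-chromosome
size errors are ~1%; these propagate linearly into every downstream kb
coordinate, which is why recovery scoring compares positions after
normalising by chromosome size.

## Conserved-block detection

Markers carry exact reference coordinates but only coarse target order:
FISH places a locus in a band, and only specially co-hybridised probe pairs
(breakpoint-flanking genes) are ordered within a band.  The detector
therefore works reference-space first, genome-wide:

* Per reference chromosome, markers with FISH-resolved order form a
  *skeleton*; walking it in reference order, each sustained direction
  change of the resolved order is a rearrangement boundary.  At a
  direction change the vertex marker joins the side it is closer to in
  FISH order — the terminal probe of an inverted segment is order-close to
  the segment's interior, while a junction jumping to a distant region is
  not.  Band-only markers then join the run whose reference interval holds
  them.  Groups with fewer than two resolved markers fall back to a greedy
  chain walk (nearest FISH-order continuation within the gap and jump
  limits).
* A reference gap larger than `max_gap_bp` (default 25 Mb) splits a run:
  content missing from that interval has moved elsewhere.  Whether it
  truly moved is checked genome-wide: if no block anywhere else covers the
  gap, the gap is a marker-sampling void and the two pieces are re-merged
  (`reconcile_gaps`).  The threshold sits between the largest plausible
  sampling void at the default marker density (~25 genes ≈ 25 Mb) and the
  smallest simulated translocation (30 genes).
* A run occupying two disjoint FISH spans with *foreign* markers strictly
  between them has been bridged across an insertion and is split.  Foreign
  means another reference chromosome, or the same chromosome at more than
  twice the gap limit — a sibling piece produced by a sampling void sits in
  the same bands and must not count.  Because order comparisons between
  two resolved probes are trustworthy at any scale, a foreign resolved
  probe strictly between two order-consecutive resolved members also
  proves interruption, whatever the band gap.
* Orphans: a lone marker strictly inside another block's FISH span
  contradicts that block.  If it lies on the block's own reference
  chromosome within the orphan window (default 10 Mb) of the position the
  block's trend predicts, it is absorbed as jitter; otherwise it is
  excluded and reported.  Markers with no reference coordinate anywhere are
  reported as unplaceable.

Orientation is the sign of the covariance between members' FISH order and
reference position; blocks confined to a single band stay `unknown`, with
member order retained as in the reference.  Block *extents* estimate
conserved content: boundaries shared with a reference-adjacent neighbour go
to the midpoint of the facing terminal markers; other boundaries stay at
the terminal marker (probe selection deliberately targets block ends);
single-member extents are floored at 1 Mb.  Cumulative extents scaled to
the chromosome's Mb size place the breakpoints; explicit gap blocks with a
fixed target span can absorb regions where no orthologous content is
identifiable.

## Geometry

The centromere is the breakpoint between the last block with p-arm FISH
evidence and the first with q-arm evidence; when both arms' evidence falls
in one block, the reference midpoint of the two flanking markers is
affinely rescaled (orientation-aware) onto the block's target extent.  Arm
cM lengths start proportional to Mb lengths; if the implied centromere cM
falls outside the flanking markers' interval it is moved the minimal
distance inside, with a 0.01 cM margin, conserving the chromosome total.
A published karyotype arm ratio can replace the split when no block
evidence exists; the unrounded value is reported.  Idiogram band fractions
are measured from each arm's outer end (p: from the p-telomere; q: from
the centromere) and interpolated linearly within the arm's kb length.

## Integration

Per chromosome, in order: FISH seeding (band-interval midpoints),
comparative fine-tuning (orientation-aware affine transform of reference
positions onto the block's target extent, clamped to the assigned band
interval), linkage anchoring (`cM' = cM + m%/100 × map length`, with
`ptr`/`qtr` appended), breakpoints, and landmarks.  Loci mapped by both
FISH and linkage become kb/cM anchors after a consistency filter: the
longest subsequence that is strictly increasing in kb and non-decreasing in
cM (and consistent with the landmarks) is kept; the remainder are reported
as order conflicts and their cM re-interpolated — the physical FISH order
always wins.  Linkage-only loci get kb by cM-proportional placement
between the nearest anchors; FISH-only loci and breakpoints get cM by
piecewise-linear interpolation.  Ties at one kb are ordered ptr first, then
FISH > linkage > breakpoint > landmark, then cM, then locus name; qtr
closes the map.  Co-located loci are allowed and FISH loci keep their
assigned band at a shared boundary.

Band curation re-runs integration with the band clamp released (the LDB
behaviour), finds FISH loci outside their assigned band — band edges count
as inside within the 1 kb grid — and moves the nearer boundary of the
assigned band the minimal distance to cover them (+1 kb for the half-open
edge), re-tiling neighbours, which must keep at least 1 kb.  The
discrepancy count must strictly decrease every round (cap: 20); data whose
FISH order genuinely contradicts the band order cannot converge, and the
pipeline then falls back to the band-clamped integration with a warning.

## Virtual map and anchoring

Per block, all annotation genes within the reference extent (orphans
excluded; duplicate claims resolved to the preferred-reference block whose
members lie nearest) are placed by orientation-aware affine interpolation
between the nearest integrated anchors — block boundaries plus every
integrated member with a known reference position, including a centromere
placed within the block.  cM comes from the integrated anchor set, bands
from the curated tiling.  Confidence: 2 if the locus is in the integrated
map (those entries are never moved), 1 in an oriented block, 0 otherwise,
NA for landmarks.  Scaffolds with one shared gene get a chromosome and
span; two or more genes in consistent order add an orientation; genes on
several chromosomes make the scaffold ambiguous and unplaced.

## Synthetic study

The generator emulates the statistical structure the pipeline assumes.
Defaults (all in `SimulationConfig`, every draw from one seeded
`numpy.random.Generator`):

* 7 chromosomes × 300 genes, exponential inter-gene spacing with mean
  1 Mb (so ~300 Mb chromosomes, a marsupial-scale genome);
* 15 rearrangements: 9 inversions (20–45% of a chromosome's genes) and 6
  translocations (10–25%), drawn on disjoint segments — breakpoint reuse
  is the exception in karyotype evolution, and chromosome-scale events are
  what band-resolution FISH can see.  Fusions and fissions are supported
  but default to 0 so the chromosome count stays fixed;
* FISH on 20% of genes at 8 bands per chromosome (band widths from a
  Dirichlet(6) split per arm — unequal but of one visual magnitude), with
  each block's terminal genes always probed and FISH-ordered within their
  band, emulating the documented breakpoint-targeted, dual-colour probe
  strategy; fill-in probes are band-only;
* linkage on 6% of genes over the central 90% of each chromosome (8%
  leading gap defining m%, 2% trailing), Gaussian cM noise of 1 cM,
  uniform recombination at 0.7 cM/Mb (the genome-wide average of the
  published map; a telomere-weighted warp is not modelled);
* flow peaks on a 40° DNA-line with conversion 2 Mb/unit, offset 8 Mb,
  1% multiplicative distance noise, calibrated against bundled human
  chromosome sizes;
* gene-scaffolds of 1–4 consecutive genes.

True breakpoints are the junctions where reference adjacency of
consecutive target genes breaks; the truth table also records block
orientations, centromeres (the junction nearest a uniform draw in the
middle of each chromosome, or a within-block position when no junction is
there) and sizes.  `score_recovery` reports breakpoint precision/recall at
a configurable tolerance (the pipeline uses the mean inter-marker gap,
~5 Mb at default density), Spearman rank correlation of true vs inferred
gene positions per chromosome, orientation and chromosome-assignment
accuracy, and confidence-stratified position error; inferred positions are
rescaled by true/estimated chromosome size first, since the two coordinate
systems legitimately differ by the flow-karyotype estimate.

What passing these tests shows: the construction recovers chromosome-scale
rearrangement structure and produces position-faithful maps when its
assumptions hold — clean large conserved segments, probes at block ends,
roughly uniform recombination.  What it does not show: performance under
heavy breakpoint reuse or many sub-band rearrangements (largely invisible
to band-resolution FISH by construction), sequence-level effects (repeats,
assembly errors in the reference), sex-specific recombination, or FISH
assignment errors, none of which are modelled.

## Numerical and degenerate-case choices

Problem sizes follow the default study (2,100 genes, ~500 markers); the
complete pipeline runs in about a second, and the whole test suite in well
under a minute.  Landmarks use fixed names `ptr`/`cen`/`qtr`.  Input files
are tab-separated with `#` comments; locus name collisions within one file
are an error.  Deterministic tie-breaks are used everywhere (stable sorts
with explicit keys); reruns with the same inputs are byte-identical, and
the run manifest records a config hash for that purpose.  A chromosome
with no linkage data integrates FISH-only with interpolated cM spanning
the full genetic length; a chromosome whose breakpoints cannot be
estimated can be given explicit gap blocks or an arm-ratio fallback.
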