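"""Interpolate unmapped genes into the virtual map with confidence tiers.

After integration, every annotation gene inside a conserved block is given
a position between its nearest mapped anchors.  Confidence 2 marks loci
actually mapped in the target species (the immutable backbone), 1 marks
genes interpolated in an oriented block, 0 in an unoriented block.
"""

from collections import Counter

from mapweaver import SimulationConfig, run_synthetic

result, dataset = run_synthetic(SimulationConfig(seed=0))

total = Counter()
for chrom, cres in result.chromosomes.items():
    total.update(e.confidence for e in cres.virtual)

print("virtual-map entries by confidence level (all chromosomes):")
print(f"  level 2 (mapped in target):        {total[2]}")
print(f"  level 1 (oriented block):          {total[1]}")
print(f"  level 0 (unoriented block):        {total[0]}")
print(f"  landmarks/breakpoints (NA):        {total[None]}")

rec = result.recovery
print(f"\nscored against the generator's truth: position Spearman rho = "
      f"{rec.spearman_rho:.4f}; mean |error| by confidence level (kb): "
      f"{ {k: round(v) for k, v in rec.per_confidence_error_kb.items()} }")
print("higher confidence does not guarantee smaller error on any one locus, "
      "but every tier tracks the truth closely when block structure is "
      "recovered correctly.")
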