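"""Organisation report for the S. roscoffensis mitochondrial annotation.

Loads the shipped coordinate table (GenBank HM237350), runs the intergenic
census, overlap detection, gene-content check and strand partition, and
prints the headline numbers: 34 genes (12 protein-coding, 2 rRNA, 20 tRNA)
on a 14803-bp circle, 29 non-coding regions of 1-137 bp, no overlaps, and
atp8 plus both leucine tRNAs missing from the canonical bilaterian set.
"""

from mitokit.datasets import load_roscoffensis
from mitokit.model import circular_gap
from mitokit.report import (
    detect_overlaps,
    gene_content_check,
    intergenic_census,
    strand_partition,
)

genome = load_roscoffensis()
print(f"{genome.identifier}: {genome.length} bp, circular={genome.circular}")
counts = {cls: len(genome.features_of_class(cls)) for cls in ("PCG", "rRNA", "tRNA")}
print(f"gene counts: {counts}")

census = intergenic_census(genome)
print(f"non-coding regions: {census.count} "
      f"(shortest {census.min_len} bp, longest {census.max_len} bp)")
wrap = census.regions[-1]
print(f"segment through the origin: {wrap.length} bp between "
      f"{wrap.flanking[0]} and {wrap.flanking[1]}")

print(f"overlapping gene pairs: {len(detect_overlaps(genome))}")

missing, extra = gene_content_check(genome)
print(f"missing vs canonical bilaterian complement: {sorted(missing)}; "
      f"extra: {extra}")

parts = strand_partition(genome)
print(f"plus-strand protein/rRNA genes: {sorted(parts['+']['PCG'] + parts['+']['rRNA'])}")
print(f"plus-strand tRNAs: {len(parts['+']['tRNA'])}, "
      f"minus-strand tRNAs: {len(parts['-']['tRNA'])}")

by_name = {f.name: f for f in genome.features}
gap = circular_gap(by_name["cox1"], by_name["trnF"], genome.length)
print(f"worked example: {gap} bp between the end of cox1 and the start of trnF")
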