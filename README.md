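# mitokit

Comparative analysis of animal mitochondrial genomes, built around the kind
of questions a newly sequenced mitogenome raises: what does its annotation
look like as a whole (gene content, strand usage, intergenic structure,
composition, repeats), do its tRNAs still fold into cloverleaves, and how
does its gene order relate to other genomes?  The package grew out of the
analysis of the acoel flatworm *Symsagittifera roscoffensis* mitogenome
(GenBank HM237350, 14803 bp), whose annotation table ships as a fixture,
and is aimed at people doing mitogenomics and gene-order phylogenetics.

## What it computes

* **Annotation statistics** on 1-based, closed-interval circular
  coordinates: per-gene lengths, the census of maximal non-coding regions
  (including the segment through the origin), overlap detection, gene
  content against a reference complement (canonical bilaterian:
  13 protein-coding genes, 2 rRNAs, 22 tRNAs), strand partition, start/stop
  codons, and maximal exact direct repeats.
* **Composition and strand skews**: base frequencies and
  AT skew = (A−T)/(A+T), GC skew = (G−C)/(G+C), whole-genome on the plus
  strand and per gene on the coding strand.
* **Gene-order comparison** on signed circular permutations of the
  protein-coding + rRNA genes: **breakpoint distance** (signed adjacencies
  of one genome absent from the other, reading direction identified) and
  **common intervals** (gene sets contiguous in both circles, irrespective
  of internal order or orientation).  On a circle a set is contiguous
  exactly when its complement is, so singletons and their complements are
  trivial; the default counts distinct sets of size 2..n−2, which is what
  makes a count of zero meaningful for totally scrambled genomes.  All
  counting conventions are explicit and sweepable.
* **tRNA cloverleaf validation**: a deterministic folder that scores
  acceptor/DHU/anticodon/TψC arm arrangements by hydrogen bonds with
  mismatch, geometry and anticodon-loop-motif terms, tolerating the missing
  DHU or TψC arms typical of mitochondrial tRNAs; plus a whole-genome
  scanner with anticodon-identity assignment.
* **A ground-truthed simulator** that generates AT-rich annotated circular
  genomes with planted gaps, codons, cloverleaf tRNAs and tandem repeats,
  so every analysis above can be tested against a known answer, and a
  gene-order scrambler (transpositions, inversions, TDRL events).

## Worked example

```python
from mitokit.datasets import load_gene_orders, load_roscoffensis
from mitokit.geneorder import compare
from mitokit.report import gene_content_check, intergenic_census

genome = load_roscoffensis()          # the published annotation, 14803 bp
census = intergenic_census(genome)
print(census.count, census.min_len, census.max_len)
# 29 1 137   -> 29 non-coding regions of 1-137 bp tile the circle exactly

print(sorted(gene_content_check(genome)[0]))
# ['atp8', 'trnL-CUN', 'trnL-UUR']   -> genes absent vs the bilaterian set

sr, fasciola, ground_pattern = load_gene_orders()
result = compare(sr, fasciola)
print(result.common_interval_count, result.breakpoint_distance)
# 2 14   -> only {cox1, nad3} (and its complement) is a shared block, and
#           not a single signed adjacency survives between the two genomes
```

The `examples/` directory holds one short narrative script per capability
(genome report, skews, gene-order comparison, tRNA scanning, simulation);
each builds or loads a small input, runs the method and prints what the
numbers mean.  A thin command-line layer exposes the same operations
(`mitokit report|skew|orders|compare|trnascan|simulate|annotate`).

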