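# Methods

## Coordinate model

All coordinates are 1-based closed intervals on a circular molecule, the
convention of GenBank flat files and printed genome-organisation tables;
position n+1 wraps to 1.  Feature length is `end − start + 1`; the gap
between consecutive features is `next.start − prev.end − 1`, computed
through the origin for the last→first pair.  A negative gap signals an
overlap and is reported, never raised.  Features spanning the origin are
rejected in this version (none occur in the shipped data); conversion to
and from other conventions happens only at I/O boundaries (Biopython's
0-based half-open locations).

The shipped *S. roscoffensis* fixture is a transcription of the published
organisation table for GenBank HM237350 (coordinates and strands only; the
sequence itself is not redistributed).  Two discrepancies internal to the
source are recorded rather than resolved:

* the printed intergenic value after trnT is 66, but with genome length
  14803 and trnT ending at 14739 the wrap gap computes to 64; the census
  uses computed values, and the circle then tiles exactly
  (14043 feature bp + 760 gap bp = 14803);
* the narrative count of "thirty" non-coding regions is not derivable from
  the table, whose intergenic column contains exactly 29 positive entries
  (28 internal gaps plus the wrap entry).  The census therefore reports 29
  regions of 1–137 bp.  Counting the wrap segment *in addition to* the 29
  printed positives would double-count the final table row and break the
  tiling identity.

## Non-coding census, overlaps, content

The census takes the union of annotated intervals (so nested or overlapping
features never resurrect covered bases) and emits every maximal uncovered
circular segment with its flanking genes.  Overlap detection reduces to
linear interval intersection because origin-spanning features are excluded.
Gene content is a set difference against a reference complement loaded from
YAML (canonical bilaterian by default; a platyhelminth-style set without
atp8 ships alongside), with duplicated names surfaced as extras.

## Composition and skews

AT skew = (A−T)/(A+T), GC skew = (G−C)/(G+C).  Whole-genome statistics are
computed on the plus strand; per-gene statistics default to each gene's
coding strand, with a `plus` option, because the source table does not
state its per-gene convention and the deposited sequence (needed to decide
it empirically) is not redistributed — the coding-strand default is the
common choice in mitogenomics.  Ambiguity codes are excluded from all
numerators and denominators; a zero denominator yields a flagged undefined
value.  Display rounding is one decimal for percentages and two for skews;
raw values are retained in JSON.

## Direct repeats

`find_direct_repeats` reports maximal exact direct repeats (tandem or
dispersed): seeds of the minimum unit length are grouped by occurrence,
then extended left and right while *all* copies remain intact.  Exact
matching only; the default minimum unit of 8 bp reflects that shorter hits
are noise in AT-rich sequence (smaller values are accepted for toy
inputs).  Tests pin the finder to an independently written quadratic
oracle on inputs up to 2 kb.

## Gene-order metrics

Gene orders are signed circular permutations of the protein-coding + rRNA
genes, read in ascending plus-strand coordinate order (tRNAs translocate
too frequently to be informative).  Unequal gene content is handled only by
explicit restriction to the shared set.

*Breakpoint distance* counts the signed adjacencies of one order absent
from the other; an adjacency and its reverse-strand reading are
identified, so the distance is invariant under rotation and reflection and
is zero exactly when the two circles are equal up to those symmetries.

*Common intervals* are distinct gene sets circularly contiguous in both
orders, orientation ignored.  On a circle a set is contiguous iff its
complement is, so every singleton *and* every size-(n−1) set is trivially
common to any pair of genomes.  The shipped default therefore counts sizes
2..n−2 — under it a fully scrambled pair can reach zero, and the
*S. roscoffensis* / *F. hepatica* pair yields exactly the two published
intervals, {cox1, nad3} and its complement, which validates both the
shipped Fasciola transcription (NC_002546) and the convention.  All
conventions (circular/linear, size bounds including n−1 and n,
set-counting vs window-counting) remain available and sweepable.

The published self-comparison maximum of 176 common intervals for the
14-gene order is not reproduced by any convention in the grid: circular
set-counting gives 154 (sizes 2..n−2), 168 (2..n−1), 182/183 (with
singletons/full set), window-counting up to 196, linear counting 90–105.
The calibration sweep documents this and pins the oracle-validated default,
whose self-count (154) is what the package reports.  No gene order for the
*Schistosoma* comparison ships: the publication names no accession for it,
and the value printed for it (zero common intervals) is instead shown to be
attainable under the default convention with a constructed scrambled pair.

The scrambler supports the rearrangement types common in mitochondrial
evolution — segment transposition, signed inversion, and tandem
duplication–random loss (duplicate the order, keep each gene in exactly one
copy) — and returns an event log.

## tRNA cloverleaf folding

A candidate span is parsed as acceptor-5′ | spacer (canonically 2 nt) | DHU
arm | spacer (1 nt) | anticodon arm | variable loop | TψC arm |
acceptor-3′, where either the DHU or the TψC arm may be replaced by an
unpaired stretch (both only with an explicit flag).  Geometry bounds:
acceptor 6–7 bp; DHU stem 2–4, loop 3–10 (replacement gap 2–10 when
absent); anticodon stem 3–5, loop 5/7/9 with the anticodon centred;
variable loop 2–23 (4–30 merged when TψC is absent); TψC stem 2–5, loop
3–9.  These spans cover the truncated stems and enlarged loops of real
mitochondrial tRNAs while keeping the search finite.

Scoring sums hydrogen bonds over intended stem positions (G·C 3, A·T 2,
G·T wobble 0.5) and subtracts 1.5 per stem mismatch, 0.5 per nt of loop- or
variable-loop-size deviation from canonical, and 1.0 per non-canonical
spacer; a +2 completeness bonus is granted per full-length perfectly paired
stem and +3 for the universal anticodon-loop motif (U immediately 5′ of the
anticodon, purine immediately 3′).  An arm whose stem pairs in fewer than
half its positions is treated as absent.  The heavy wobble discount, the
geometry priors and the motif are what separate genuine cloverleaves from
the near-perfect spurious folds that AT-rich random sequence otherwise
produces; a flat paired-bases score has essentially no specificity at
mitogenome scale.  Scores are sums of dyadic rationals, so the vectorized
whole-genome scan and the per-candidate enumeration agree exactly, and
folding is a deterministic, context-free function of the span (ties break
toward the earliest arrangement in a fixed enumeration order).

Thresholds are calibrated on simulated sequence at the default AT-rich
composition: the fold threshold (25) passes ≈2–3 % of random 70-mers
(requirement: <5 %) while planted tRNAs with up to two stem mismatches
score ≥32; the genome-scan threshold (40) sits below every planted tRNA
(≥43 across seeds) and above the bulk of random structure.  The scanner
additionally requires a conventional mitochondrial anticodon — the
identity-assignment step of any tRNA annotation pipeline — and resolves
overlaps greedily by score.  Residual false positives of ≈1–2 per 15 kb
genome at the scan threshold remain and score below every planted tRNA;
this false-positive floor is an inherent property of structure-only
detection in AT-rich sequence (probabilistic covariance models are out of
scope), mirroring the manual curation real mitogenome annotations need.

## The simulator

`roscoffensis_like()` encodes the study conditions: a 14803-bp circle with
composition (A, T, G, C) = (0.386, 0.367, 0.128, 0.119); the real gene
complement (12 protein-coding genes with the published lengths, 2 rRNAs,
20 tRNAs) and strand partition; planted intergenic gaps of 137, 1 and five
zeros with geometric noise (mean 20 bp) scaled so the circle closes
exactly; start codons drawn from ATG/ATT/ATA/ATC and stops TAA (90 %) /
TAG; the published 42-bp repeat unit planted twice inside nad6; and the
observed arm losses (DHU absent in trnS-AGY and trnD; TψC absent in trnA,
-H, -I, -M, -T, -E, -Y).  Sequence is i.i.d. per base on the plus strand —
no codon model, since the composition claims the generator backs need only
base frequencies; structured elements overwrite their spans.  tRNA stems
are modestly GC-enriched (a quarter of the A/T probability mass moved to
G/C), as stems of structural RNAs are, and anticodon loops carry the
universal U33/purine-37 motif.

Ground truth must be recoverable to be usable: tRNA draws are rejected
until the planted geometry is the folder's unique optimum and strictly
dominates every sub-window and reverse-complement reading (a hairpin's
reverse complement is also a hairpin), and after assembly free context
bases are redrawn until each planted span strictly beats every overlapping
window that greedy selection would otherwise keep — the neighbourhood is
taken circularly, so plants at the origin are covered.  Repeat plants
similarly get flank columns forced to disagree so the planted unit is the
maximal repeat.  What passing tests on this generator do *not* show: real
tRNAs are not unique fold optima by construction, real repeats are not
exact, and real genomes have codon structure, so detector performance on
simulated data bounds idealised, not field, behaviour.

## Problem sizes and determinism

Tests and the acceptance script run at desk scale: gene-order oracle
sweeps use 10⁴ random pairs at n ≤ 8 against subset-enumeration oracles;
the tRNA recovery sweep uses 500 single-plant genomes of 420 bp with 0–2
planted mismatches; repeat-finder oracle checks go up to 2 kb; the
end-to-end pipeline check runs on the seed-1 default genome.  Every random
draw flows from a single seeded NumPy generator per operation, so all
outputs — including written FASTA/GenBank/JSON bundles — are byte-identical
across runs and platforms.
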