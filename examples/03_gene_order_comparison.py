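"""Gene-order comparison via common intervals and breakpoint distances.

Gene orders are signed circular permutations of the protein-coding + rRNA
genes (tRNAs translocate too often to be informative).  A common interval
is a set of genes occupying a contiguous arc in both genomes regardless of
internal order; the breakpoint distance counts signed adjacencies of one
genome missing from the other.  The shipped orders give the published
S. roscoffensis vs Fasciola hepatica count of 2 ({cox1, nad3} and its
complement), while the bilaterian ground pattern scores higher, and the
convention sweep documents what a self-comparison can maximally reach.
"""

from mitokit.datasets import load_gene_orders
from mitokit.geneorder import (
    common_intervals,
    compare,
    convention_sweep,
    pairwise_matrix,
    restrict_to_shared,
)

sr, fasciola, ground = load_gene_orders()
print(sr, "\n" + str(fasciola), "\n" + str(ground), sep="\n")

result = compare(sr, fasciola)
print(f"\nS. roscoffensis vs F. hepatica ({result.convention.describe()}):")
print(f"  common intervals: {result.common_interval_count} -> "
      f"{[sorted(s) for s in result.intervals if len(s) == 2]} and its complement")
print(f"  breakpoint distance: {result.breakpoint_distance} of n={result.n}")

a, g = restrict_to_shared(sr, ground)  # the ground pattern carries atp8
count, _ = common_intervals(a, g)
print(f"vs bilaterian ground pattern (shared n={len(a)}): {count} common intervals")

matrix, long_table = pairwise_matrix([sr, fasciola, ground], metric="ci")
print("\npairwise common-interval matrix:")
print(matrix.to_string())

print("\nself-comparison maxima under different counting conventions:")
for convention, value in convention_sweep(sr).items():
    print(f"  {convention:28s} {value}")
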