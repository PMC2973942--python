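"""Base composition and AT/GC strand skews on a simulated genome.

Generates the default AT-rich study genome (a real annotated sequence would
work the same through mitokit.io.read_genbank), then prints whole-genome
base frequencies, the two skew statistics, per-gene coding-strand skews and
the terminal codons of each protein gene.  AT skew = (A-T)/(A+T) and
GC skew = (G-C)/(G+C); values near zero mean no strand asymmetry.
"""

from mitokit.composition import genome_skew_report, per_gene_skews, terminal_codons
from mitokit.synthetic import generate, roscoffensis_like

genome, truth = generate(roscoffensis_like(seed=1))
report = genome_skew_report(genome).rounded()
print(f"{genome.identifier}: {genome.length} bp")
print(f"frequencies: A {report['a_pct']}%  T {report['t_pct']}%  "
      f"G {report['g_pct']}%  C {report['c_pct']}%  (A+T {report['at_content']}%)")
print(f"whole-strand skews: AT {report['at_skew']}  GC {report['gc_skew']}")

print("\nper-gene coding-strand skews (protein + rRNA genes):")
for gene in per_gene_skews(genome, convention="coding"):
    shown = gene.rounded()
    print(f"  {shown['scope']:6s} GC {shown['gc_skew']:+.2f}  AT {shown['at_skew']:+.2f}")

print("\nstart/stop codons:")
for feature in genome.features_of_class("PCG"):
    start, stop = terminal_codons(genome, feature)
    print(f"  {feature.name:6s} {start} ... {stop}")
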