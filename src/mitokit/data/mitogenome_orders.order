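# Mitochondrial gene orders (protein-coding + rRNA genes, signed, circular).
# One genome per line: identifier followed by gene tokens in plus-strand
# coordinate order; a leading '-' marks a minus-strand gene.
#
# s_roscoffensis: from the genome organisation table of GenBank HM237350.
# f_hepatica: Fasciola hepatica, NC_002546 (classic trematode arrangement).
# bilaterian_ground_pattern: putative bilaterian/deuterostome ground pattern
#   (human-like arrangement, atp8 present).
s_roscoffensis	cox1 cox2 cox3 atp6 rrnS -nad5 rrnL nad6 nad4 -nad2 -cytb -nad1 -nad4L -nad3
f_hepatica	cox3 cytb nad4L nad4 atp6 nad2 nad1 nad3 cox1 rrnL rrnS cox2 nad6 nad5
bilaterian_ground_pattern	rrnS rrnL nad1 nad2 cox1 cox2 atp8 atp6 cox3 nad3 nad4L nad4 nad5 -nad6 cytb
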