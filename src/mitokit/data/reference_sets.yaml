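# Reference mitochondrial gene complements used by gene_content_check.
# Names follow the normalized trnX / cox1 vocabulary; serine and leucine
# tRNA isoacceptors carry their codon-family suffix.
bilaterian_canonical:
  PCG: [cox1, cox2, cox3, cytb, atp6, atp8,
        nad1, nad2, nad3, nad4, nad4L, nad5, nad6]
  rRNA: [rrnS, rrnL]
  tRNA: [trnA, trnC, trnD, trnE, trnF, trnG, trnH, trnI, trnK,
         trnL-CUN, trnL-UUR, trnM, trnN, trnP, trnQ, trnR,
         trnS-AGY, trnS-UCN, trnT, trnV, trnW, trnY]
# Platyhelminth-style complement: atp8 lost.
platyhelminth:
  PCG: [cox1, cox2, cox3, cytb, atp6,
        nad1, nad2, nad3, nad4, nad4L, nad5, nad6]
  rRNA: [rrnS, rrnL]
  tRNA: [trnA, trnC, trnD, trnE, trnF, trnG, trnH, trnI, trnK,
         trnL-CUN, trnL-UUR, trnM, trnN, trnP, trnQ, trnR,
         trnS-AGY, trnS-UCN, trnT, trnV, trnW, trnY]
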