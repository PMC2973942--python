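# Symsagittifera roscoffensis mitochondrial genome organisation (GenBank HM237350)
# genome_length=14803 circular=true
gene	class	strand	start	end
cox1	PCG	+	1	1551
trnF	tRNA	+	1591	1651
cox2	PCG	+	1688	2428
trnD	tRNA	-	2449	2499
trnI	tRNA	-	2533	2594
cox3	PCG	+	2603	3394
trnY	tRNA	+	3396	3451
atp6	PCG	+	3459	4160
trnV	tRNA	+	4169	4237
trnQ	tRNA	-	4241	4303
trnN	tRNA	+	4304	4375
trnH	tRNA	+	4395	4456
trnE	tRNA	+	4462	4527
trnK	tRNA	+	4555	4621
trnA	tRNA	+	4624	4688
rrnS	rRNA	+	4689	5452
trnR	tRNA	+	5453	5514
nad5	PCG	-	5534	7309
trnW	tRNA	-	7336	7400
trnS-AGY	tRNA	+	7409	7475
rrnL	rRNA	+	7476	8417
trnC	tRNA	-	8418	8478
trnS-UCN	tRNA	+	8483	8546
trnM	tRNA	+	8554	8602
nad6	PCG	+	8616	9095
trnG	tRNA	+	9106	9170
nad4	PCG	+	9174	10523
nad2	PCG	-	10661	11650
cytb	PCG	-	11721	12881
nad1	PCG	-	12918	13787
nad4L	PCG	-	13893	14162
trnP	tRNA	-	14167	14234
nad3	PCG	-	14262	14654
trnT	tRNA	+	14674	14739
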