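# Annotated mitochondrial gene table of Thrips palmi (GenBank MH253898),
# 15,333 bp circular genome, 39 features (13 PCGs, 22 tRNAs, 2 rRNAs, 2 CRs).
# Coordinates are 1-based inclusive; "start-end+N" denotes wrap past the origin.
# ign = intergenic nucleotides to the NEXT feature (negative = overlap);
# "." = not stated (the wrap junction).
name	category	strand	location	size	anticodon	start_codon	stop_codon	ign
nad5	PCG	-	176-1828	1653	.	ATT	TAA	29
trnH	tRNA	-	1858-1919	62	CAC	.	.	2
nad4	PCG	-	1922-3241	1320	.	ATT	TAA	-7
nad4l	PCG	-	3235-3510	276	.	ATG	TAG	34
trnC	tRNA	+	3545-3606	62	UGC	.	.	19
nad6	PCG	+	3626-4111	486	.	ATT	TAA	43
trnV	tRNA	+	4155-4214	60	GUA	.	.	0
rrnL	rRNA	+	4215-5325	1111	.	.	.	27
cox1	PCG	+	5353-6915	1563	.	TTG	TAA	-1
nad3	PCG	+	6915-7319	405	.	ATG	TAA	12
cox2	PCG	+	7332-7988	657	.	ATA	TAA	5
trnG	tRNA	+	7994-8057	64	GGA	.	.	-1
trnK	tRNA	+	8057-8120	64	AAA	.	.	13
cox3	PCG	+	8134-8916	783	.	ATA	TAA	4
trnN	tRNA	+	8921-8983	63	AAC	.	.	-3
trnT	tRNA	+	8981-9044	64	ACA	.	.	7
trnS1	tRNA	+	9052-9108	57	AGA	.	.	15
trnL1	tRNA	+	9124-9188	65	CUA	.	.	3
CR2	CR	+	9192-9329	138	.	.	.	1
trnP	tRNA	-	9331-9394	64	CCA	.	.	23
trnI	tRNA	+	9418-9481	64	AUC	.	.	1
cytb	PCG	+	9483-10595	1113	.	ATA	TAA	8
trnY	tRNA	-	10604-10666	63	UAC	.	.	37
nad2	PCG	+	10704-11726	1023	.	ATA	TAA	-50
trnW	tRNA	+	11677-11738	62	UGA	.	.	0
nad1	PCG	+	11739-12662	924	.	ATA	TAA	-4
trnM	tRNA	+	12659-12719	61	AUG	.	.	1
trnA	tRNA	+	12721-12782	62	GCA	.	.	-1
trnF	tRNA	+	12782-12844	63	UUC	.	.	-2
rrnS	rRNA	+	12843-13570	728	.	.	.	-1
atp8	PCG	+	13570-13738	169	.	ATA	T(TT)	-7
atp6	PCG	+	13732-14391	660	.	ATT	TAA	-1
trnQ	tRNA	+	14391-14458	68	CAA	.	.	41
trnS2	tRNA	+	14500-14564	65	UCA	.	.	1
trnD	tRNA	+	14566-14633	68	GAC	.	.	46
trnL2	tRNA	+	14680-14744	65	CUA	.	.	99
trnE	tRNA	+	14844-14905	62	GAA	.	.	49
trnR	tRNA	+	14955-15019	65	CGA	.	.	0
CR1	CR	+	15020-15333+175	489	.	.	.	.
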