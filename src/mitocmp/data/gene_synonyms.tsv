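# GenBank gene/product name -> canonical symbol mapping (editable).
# Matching is case-insensitive on the alias column.
alias	canonical
ND1	nad1
ND2	nad2
ND3	nad3
ND4	nad4
ND4L	nad4l
NAD4L	nad4l
ND5	nad5
ND6	nad6
NADH1	nad1
NADH2	nad2
NADH3	nad3
NADH4	nad4
NADH5	nad5
NADH6	nad6
COI	cox1
COII	cox2
COIII	cox3
COX1	cox1
COX2	cox2
COX3	cox3
CO1	cox1
CO2	cox2
CO3	cox3
ATP6	atp6
ATP8	atp8
ATPASE6	atp6
ATPASE8	atp8
CYTB	cytb
COB	cytb
CYB	cytb
12S	rrnS
16S	rrnL
SRRNA	rrnS
LRRNA	rrnL
12S RIBOSOMAL RNA	rrnS
16S RIBOSOMAL RNA	rrnL
S-RRNA	rrnS
L-RRNA	rrnL
RRNS	rrnS
RRNL	rrnL
D-LOOP	CR1
CONTROL REGION	CR1
TRNA-ALA	trnA
TRNA-ARG	trnR
TRNA-ASN	trnN
TRNA-ASP	trnD
TRNA-CYS	trnC
TRNA-GLN	trnQ
TRNA-GLU	trnE
TRNA-GLY	trnG
TRNA-HIS	trnH
TRNA-ILE	trnI
TRNA-LEU	trnL2
TRNA-LYS	trnK
TRNA-MET	trnM
TRNA-PHE	trnF
TRNA-PRO	trnP
TRNA-SER	trnS1
TRNA-THR	trnT
TRNA-TRP	trnW
TRNA-TYR	trnY
TRNA-VAL	trnV
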