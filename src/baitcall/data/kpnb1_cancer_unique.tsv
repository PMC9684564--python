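accession	protein_name	gene_name	molecular_weight_kda	functional_group
P62826	GTP-binding nuclear protein Ran	RAN	26.224	Nuclear transport
P18124	60S ribosomal protein L7	RPL7	29.225	Ribosomal proteins
P62753	40S ribosomal protein S6	RPS6	28.68	Ribosomal proteins
P27635	60S ribosomal protein L10	RPL10	18.565	Ribosomal proteins
G3V203	60S ribosomal protein L18	RPL18	18.756	Ribosomal proteins
P62701	40S ribosomal protein S4, X isoform	RPS4X	29.597	Ribosomal proteins
M0QZC5	40S ribosomal protein S11	RPS11	13.997	Ribosomal proteins
P40429	60S ribosomal protein L13A	RPL13A	23.577	Ribosomal proteins
Q1KMD3	Heterogeneous nuclear ribonucleoprotein U-like protein 2	HNRNPUL2	84.69	Heterogeneous nuclear ribonucleoproteins
P31942	Heterogeneous nuclear ribonucleoprotein H3	HNRNPH3	36.926	Heterogeneous nuclear ribonucleoproteins
Q6UN15	Pre-mRNA 3-end-processing factor FIP1	FIP1L1	66.526	RNA binding/processing
Q8N684	Cleavage and polyadenylation specificity factor subunit 7	CPSF7	41.265	Cleavage and polyadenylation
J3KTL2	Serine/arginine-rich splicing factor 1	SRSF1	28.329	Spliceosomal component
A0A087X2D0	Serine/arginine-rich splicing factor 3	SRSF3	10.32	Spliceosomal component
P35658	Nuclear pore complex protein Nup214	NUP214	213.62	NPC component
Q96AE4	Far upstream element-binding protein 1	FUBP1	67.56	ssDNA binding/stabilization
F8W1R7	Myosin light polypeptide 6	MYL6	14.436	Motor protein
Q8IX12	Cell division cycle and apoptosis regulator protein 1	CCAR1	132.82	Regulation of cell growth
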