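accession	protein_name	gene_name	molecular_weight_kda	functional_group
Q14974	Importin subunit beta-1	KPNB1	97.169	Nuclear import
J3QLE5	Small nuclear ribonucleoprotein-associated protein N	SNRPN	17.546	Spliceosomal component
P08621	U1 small nuclear ribonucleoprotein 70 kDa	SNRNP70	51.556	Spliceosomal component
P09012	U1 small nuclear ribonucleoprotein A	SNRPA	31.279	Spliceosomal component
P62316	Small nuclear ribonucleoprotein Sm D2	SNRPD2	13.527	Spliceosomal component
P62318	Small nuclear ribonucleoprotein Sm D3	SNRPD3	13.916	Spliceosomal component
Q13435	Splicing factor 3B subunit 2	SF3B2	100.23	Spliceosomal component
Q15637	Splicing factor 1	SF1	68.329	Spliceosomal component
A0A087WUK2	Heterogeneous nuclear ribonucleoprotein D-like	HNRNPDL	40.04	Heterogeneous nuclear ribonucleoproteins
A0A0A0MRA5	Heterogeneous nuclear ribonucleoprotein U-like protein 1	HNRNPUL1	85.939	Heterogeneous nuclear ribonucleoproteins
D6R9P3	Heterogeneous nuclear ribonucleoprotein A/B	HNRNPAB	30.302	Heterogeneous nuclear ribonucleoproteins
O43390	Heterogeneous nuclear ribonucleoprotein R	HNRNPR	70.942	Heterogeneous nuclear ribonucleoproteins
Q13151	Heterogeneous nuclear ribonucleoprotein A0	HNRNPA0	30.84	Heterogeneous nuclear ribonucleoproteins
B0QYK0	RNA-binding protein EWS	EWSR1	64.929	RNA binding/processing
P35637	RNA-binding protein FUS	FUS	53.425	RNA binding/processing
Q15717	ELAV-like protein 1	ELAVL1	36.091	RNA binding/processing
Q9Y224	UPF0568 protein C14orf166	C14orf166	28.068	RNA binding/processing
A0A0D9SFB3	ATP-dependent RNA helicase DDX3X	DDX3X	70.839	RNA helicases
A0A1X7SBZ2	Probable ATP-dependent RNA helicase DDX17	DDX17	80.253	RNA helicases
P26196	Probable ATP-dependent RNA helicase DDX6	DDX6	54.416	RNA helicases
J3KTA4	Probable ATP-dependent RNA helicase DDX5	DDX5	69.086	RNA helicases
F8WJN3	Cleavage and polyadenylation specificity factor subunit 6	CPSF6	52.269	Cleavage and polyadenylation
Q05048	Cleavage stimulation factor subunit 1	CSTF1	48.357	Cleavage and polyadenylation
O43809	Cleavage and polyadenylation specificity factor subunit 5	NUDT21	26.227	Cleavage and polyadenylation
M0R3D6	60S ribosomal protein L18a	RPL18A	16.714	Ribosomal proteins
P62277	40S ribosomal protein S13	RPS13	17.222	Ribosomal proteins
P62899	60S ribosomal protein L31	RPL31	14.463	Ribosomal proteins
Q8N1F7	Nuclear pore complex protein Nup93	NUP93	93.487	NPC component
F5H365	Protein transport protein Sec23A	SEC23A	82.968	NPC component
P55735	Protein SEC13 homolog	SEC13	35.54	NPC component
Q96I24	Far upstream element-binding protein 3	FUBP3	61.64	ssDNA binding/stabilization
P27694	Replication protein A 70 kDa DNA-binding subunit	RPA1	68.137	ssDNA binding/stabilization
Q8TAQ2	SWI/SNF complex subunit SMARCC2	SMARCC2	132.88	SWI/SNF component
O96019	Actin-like protein 6A	ACTL6A	47.46	SWI/SNF component
Q92734	Protein TFG	TFG	43.447	Vesicle transport
A5YKK6	CCR4-NOT transcription complex subunit 1	CNOT1	266.94	Regulation of gene expression
P23258	Tubulin gamma-1 chain	TUBG1	51.169	Microtubule organization
Q86X55	Histone-arginine methyltransferase CARM1	CARM1	65.853	Methylation of arginyl residues
Q8WXF1	Paraspeckle component 1	PSPC1	58.743	Regulation of circadian clock
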