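section	item	value	value2
site	Colon	169	77.9
site	Rectal	48	22.1
sex	Male	118	54.4
sex	Female	99	45.6
age	Mean (SD)	64.8	10.1
race	Non-Hispanic white	161	74.2
race	Hispanic	14	6.5
race	Non-Hispanic black	8	3.7
race	Unknown	34	15.7
tumor_phenotype	TP53 mutated	103	47.5
tumor_phenotype	KRAS mutated	69	31.8
tumor_phenotype	BRAF mutated	21	10.1
tumor_phenotype	CIMP high	45	20.7
tumor_phenotype	MSI	29	13.4
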