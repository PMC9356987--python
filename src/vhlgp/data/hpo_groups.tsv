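# vhlgp HPO term -> combined phenotype group mapping, table version 1.0
# One term maps to exactly one group. Users may extend this table and pass
# it to load_hpo_table()/map_phenotypes(). The parent term "Hemangioblastoma"
# is assigned to CHB (not RA) and "Neuroendocrine neoplasm" to PPGL (not
# PNET), the two deliberate parent-term exceptions of the curation scheme.
hpo_id	group	label
HP:0009713	CHB	Spinal hemangioblastoma
HP:0006880	CHB	Cerebellar hemangioblastoma
HP:0010797	CHB	Hemangioblastoma
HP:0009594	RA	Retinal capillary hemangioma
HP:0002666	PPGL	Pheochromocytoma
HP:0002668	PPGL	Paraganglioma
HP:0100634	PPGL	Neuroendocrine neoplasm
HP:0005584	RCC	Renal cell carcinoma
HP:0030088	PNET	Pancreatic endocrine tumor
HP:0011854	ELST	Endolymphatic sac tumor
HP:0001737	PCT	Pancreatic cyst
HP:0002894	PCT	Neoplasm of the pancreas
HP:0000107	RCT	Renal cyst
HP:0100899	ECT	Epididymal cyst
HP:0000138	OCT	Ovarian cyst
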