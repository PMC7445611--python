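hgnc_id	symbol	name
HGNC:1097	BRAF	B-Raf proto-oncogene, serine/threonine kinase
HGNC:3236	EGFR	epidermal growth factor receptor
HGNC:6407	KRAS	KRAS proto-oncogene, GTPase
HGNC:7989	NRAS	NRAS proto-oncogene, GTPase
HGNC:11998	TP53	tumor protein p53
HGNC:8975	PIK3CA	phosphatidylinositol-4,5-bisphosphate 3-kinase catalytic subunit alpha
HGNC:427	ALK	ALK receptor tyrosine kinase
HGNC:9967	RET	ret proto-oncogene
HGNC:7029	MET	MET proto-oncogene, receptor tyrosine kinase
HGNC:3430	ERBB2	erb-b2 receptor tyrosine kinase 2
HGNC:1100	BRCA1	BRCA1 DNA repair associated
HGNC:1101	BRCA2	BRCA2 DNA repair associated
HGNC:9588	PTEN	phosphatase and tensin homolog
HGNC:583	APC	APC regulator of WNT signaling pathway
HGNC:6342	KIT	KIT proto-oncogene, receptor tyrosine kinase
HGNC:8803	PDGFRA	platelet derived growth factor receptor alpha
HGNC:5382	IDH1	isocitrate dehydrogenase (NADP(+)) 1
HGNC:5383	IDH2	isocitrate dehydrogenase (NADP(+)) 2
HGNC:3765	FLT3	fms related receptor tyrosine kinase 3
HGNC:6192	JAK2	Janus kinase 2
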