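# Worked literature examples (BTK, KISS1R, NPC1, SERPING1, MIR140 variants) with the
# VariO terms stated for them in the published RNA variation systematics.
# cds_len empty => no CDS (non-coding molecule or context-free). meta terms are
# caller-asserted (origin / splice-outcome / typing knowledge), never inferred.
variant	transcript_id	rna_class	cds_len	ref_codon	meta	expected	description
r.3g>u	BTK	mRNA	1980			VariO:0317|VariO:0312|VariO:0316	initiation codon change; transversion; causes XLA
r.1559g>a	BTK	mRNA	1980	cga		VariO:0312|VariO:0313|VariO:0315|VariO:0308	missense p.R520Q; purine transition
r.1135c>u	BTK	mRNA	1980	caa		VariO:0312|VariO:0313|VariO:0314|VariO:0310	nonsense; premature UAA mid-CDS
r.954u>c	BTK	mRNA	1980	agu		VariO:0312|VariO:0313|VariO:0314|VariO:0318	silent; S318 retained
r.777_839del	BTK	mRNA	1980			VariO:0319|VariO:0320	in-frame deletion of 63 nt / 21 residues (260-280)
c.1953del	BTK	mRNA	1980			VariO:0319|VariO:0321	out-of-frame single-base deletion; p.L652* truncation
r.1682_1683delinsa	BTK	mRNA	1980			VariO:0311|VariO:0031	out-of-frame indel (net -1)
r.1401_1402delinsuu	BTK	mRNA	1980			VariO:0311|VariO:0030	in-frame indel (net 0)
r.1812_1813insgacagu	BTK	mRNA	1980			VariO:0326|VariO:0332	in-frame insertion of 6 nt
r.1195u>c	KISS1R	mRNA	1197	uga		VariO:0312|VariO:0313|VariO:0314|VariO:0309	termination codon change; stop 399 becomes sense
c.839+5G>A	BTK	pre-mRNA			VariO:0503	VariO:0367|VariO:0369|VariO:0503	non-canonical donor-site variant causing exon skipping (r.777_839del)
c.392-2A>C	BTK	pre-mRNA				VariO:0370|VariO:0372	canonical acceptor-site variant causing r.392_520del
r.392_520del	BTK	mRNA	1980			VariO:0319|VariO:0320	in-frame deletion of 129 nt from acceptor-site variant
c.1029+384A>G	SERPING1	pre-mRNA			VariO:0504|VariO:0373|VariO:0374	VariO:0367|VariO:0369|VariO:0504|VariO:0373|VariO:0374	deep-intronic donor creation; cryptic exon inclusion (HAE)
r.1442g>c	BTK	mRNA	1980	ugu	VariO:0247	VariO:0312|VariO:0316|VariO:0308|VariO:0247	artificial construct variant p.C481S
c.2978delG	NPC1	mRNA	3834		VariO:0245|VariO:0335	VariO:0319|VariO:0321|VariO:0245|VariO:0335	frameshift deletion; transcript removed by NMD
r.24a>g	MIR140	microRNA			VariO:0478	VariO:0312|VariO:0313|VariO:0315|VariO:0478	miRNA seed variant; skeletal dysplasia
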