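# BioBrick eukaryotic part collection: 52 records (4 plasmid backbones,
# 48 insert parts; 9 previously existing, 43 new).  Backbone rows use
# backbone=none and their size is the plasmid size, not an insert size.
# Boolean columns use YES/N as in the source tables; '-' marks
# not-applicable (backbone rows).  restriction_sites lists the classical
# (non-BioBrick) enzyme sites present in each part or plasmid.
group	nickname	description	registry_id	genbank_id	backbone	size_bp	kozak	stop	frame3n	preexisting	restriction_sites	well
Backbones	pSB1A3	High copy number plasmid carrying ampicillin resistance.	pSB1A3		none	2157	-	-	-	YES		1A
Backbones	pSB1AK3	High copy number plasmid carrying ampicillin and kanamycin resistance.	pSB1AK3		none	3189	-	-	-	YES	ClaI,HindIII,SmaI,XhoI	1B
Backbones	pSB1AC3	High copy number plasmid carrying ampicillin and chloramphenicol resistance.	pSB1AC3		none	3055	-	-	-	YES	SacI,XhoI	1C
Backbones	pSB1AT3	High copy number plasmid carrying ampicillin and tetracyclin resistance.	pSB1AT3		none	3446	-	-	-	YES	BamHI,ClaI,HindIII,SalI,SphI,XhoI	1D
Construction	Kozak	Simple Kozak sequence protein head domain	BBa_J96000	JN204869	AK	12	YES	N	YES	N		1E
Construction	Stop	Tail domain with stop codons in all three frames	BBa_J96001	JN204870	AK	11	N	YES	N	N		1F
Construction	CMV	Cytomegalovirus immediate-early promoter	BBa_I712004		AK	654	N	YES	YES	YES	SacI	1G
Construction	SV40pA	Eukaryotic polyadenylation signal derived from the SV40 early poly A sequence	BBa_J52016		AK	228	N	YES	YES	YES	SphI	1H
Construction	MCS1a	Multiple cloning site version 1, first frame	BBa_J96002	JN204871	AK	32	N	N	N	N	ApaI,XhoI,BamHI,HindIII	2A
Construction	MCS1b	Multiple cloning site version 1, second frame	BBa_J96003	JN204872	AT	33	N	N	YES	N	ApaI,XhoI,BamHI,HindIII	2B
Construction	MCS1c	Multiple cloning site version 1, third frame	BBa_J96004	JN204873	AT	34	N	N	N	N	ApaI,XhoI,BamHI,HindIII	2C
Construction	MCS2a	Multiple cloning site version 2, first frame	BBa_J96005	JN204874	AT	30	N	N	YES	N	BglII,SacI,KpnI,AgeI	2D
Construction	MCS2b	Multiple cloning site version 2, second frame	BBa_J96006	JN204875	AT	31	N	N	N	N	BglII,SacI,KpnI,AgeI	2E
Construction	MCS2c	Multiple cloning site version 2, third frame	BBa_J96007	JN204876	AT	32	N	N	N	N	BglII,SacI,KpnI,AgeI	2F
Construction	MCS3a	Multiple cloning site version 3, first frame	BBa_J96008	JN204877	AC	39	N	N	YES	N	BsrGI,StuI,SalI,SphI,ClaI	2G
Construction	MCS3b	Multiple cloning site version 3, second frame	BBa_J96009	JN204878	AC	40	N	N	N	N	BsrGI,StuI,SalI,SphI,ClaI	2H
Construction	MCS3c	Multiple cloning site version 3, third frame	BBa_J96010	JN204879	AC	41	N	YES	N	N	BsrGI,StuI,SalI,SphI,ClaI	3A
Selection	FNeomycin	Resistance to G418/neomycin gene	BBa_J96011	JN204880	AK	801	YES	YES	YES	N	SphI	4A
Selection	FPuromycin	Resistance to puromycin gene	BBa_J96012	JN204881	AC	606	YES	YES	YES	N	StuI	4B
Selection	FHSTK	Herpes simplex thymidine kinase conferring toxicity to ganciclovir	BBa_J96013	JN204882	AC	1137	YES	YES	YES	N	ApaI,SmaI,SphI	4C
Reporters	tdTomato	Engineered red fluorescent protein	BBa_J96029	JN204883	AK	1425	N	N	YES	N		5A
Reporters	EGFP	Engineered green fluorescent protein	BBa_J96031	JN204884	AC	714	N	N	YES	N	BsrGI	5B
Reporters	Cerulean	Engineered cyan fluorescent protein (mCerulean)	BBa_J96032	JN204885	AC	714	N	N	YES	N	BsrGI,ClaI	5C
Reporters	EBFP2	Engineered blue fluorescent protein	BBa_J96033	JN204886	AC	714	N	N	YES	N		5D
Reporters	mCherry	Engineered red fluorescent protein	BBa_J63000		A	705	N	N	YES	YES		5E
Reporters	RLuciferase	Renilla luciferase gene	BBa_J96034	JN204887	AK	930	N	N	YES	N	BsrGI,SphI	5F
Tags	Flag	FLAG affinity tag	BBa_J96035	JN204888	AC	24	N	N	YES	N		6A
Tags	HA	HA affinity tag	BBa_J96036	JN204889	AC	27	N	N	YES	N		6B
Tags	His	His affinity tag	BBa_J96037	JN204890	AC	18	N	N	YES	N		6C
Tags	StrepII	Strep II affinity tag	BBa_J96038	JN204891	AC	24	N	N	YES	N		6D
Localization	SP	Membrane or secretion: IgK leader peptide with Kozak	BBa_J96014	JN204892	AC	69	YES	N	YES	N		7A
Localization	TMD	PDGF Receptor Transmembrane Domain	BBa_J96015	JN204893	AC	147	N	N	YES	N		7B
Localization	Myristoylation	Myristoylation signal sequence with Kozak	BBa_J96016	JN204894	AC	48	YES	N	YES	N		7C
Localization	NLS	Nuclear Localization Signal from SV40	BBa_J63008		A	21	N	N	YES	YES		7D
Recombination	Loxp	Lox p sequence	BBa_J96017	JN204895	AC	36	N	N	YES	N		8A
Recombination	Lox66	Directional lox sequence compatible with lox71	BBa_J96018	JN204896	AC	36	N	N	YES	N		8B
Recombination	Lox71	Directional lox sequence compatible with lox66	BBa_J96019	JN204897	AC	36	N	N	YES	N		8C
Cistron	IRES	Internal ribosomal entry site	BBa_J96040	JN204898	AC	504	N	YES	YES	N	ApaI,HindIII,KpnI	9A
Cistron	P2A	Self cleaving 2A peptide	BBa_J96041	JN204899	AC	42	N	N	YES	N	SmaI	9B
Cistron	T2A	Self cleaving 2A peptide	BBa_J96042	JN204900	AC	54	N	N	YES	N		9C
Cistron	PS3	Short DNA sequence for ribosome recruitment (mini-IRES)	BBa_J96043	JN204901	AC	50	N	YES	N	N	BsrGI	9D
Cistron	PS4	Short DNA sequence for ribosome recruitment (mini-IRES)	BBa_J96044	JN204902	AC	48	N	YES	YES	N		9E
Others	Linker	24 aa flexible linker, rich in Gly and Ser.	BBa_J96020	JN204903	AC	72	N	N	YES	N		10A
Others	Spacer1	Randomized DNA spacer	BBa_J96021		A	72	N	YES	YES	YES		10B
Others	Spacer2	Randomized DNA spacer	BBa_J96022	JN204904	AK	70	N	N	N	N		10C
Others	MS2	MS2 phage coat domain binding to RNA at the MS2 binding site sequence	BBa_J96023	JN204905	AK	387	N	N	YES	N	BglII,SacI,SalI	10D
Others	MS2BS	MS2 phage coat binding site sequence	BBa_J96024	JN204906	AC	39	N	N	YES	N	SalI	10E
Others	LambdaN	Lambda N peptide sequence binding to RNA at the boxB binding site	BBa_J96025	JN204907	AC	66	N	N	YES	N		10F
Others	BoxB	Lambda N peptide binding site sequence	BBa_J96026	JN204908	AC	21	N	N	YES	N	ApaI	10G
Others	TEVSite	TEV tobacco etch virus protease cleavage site	BBa_J96027	JN204909	AC	21	N	N	YES	N		10H
Others	d1PEST	Mouse ornithine decarboxylase PEST sequence, 1 hr half-life	BBa_96046	JN204910	AT	129	N	YES	YES	N		11A
Others	d2PEST	Mouse ornithine decarboxylase PEST sequence, 2 hr half-life	BBa_96047	JN204911	AT	129	N	YES	YES	N		11B
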