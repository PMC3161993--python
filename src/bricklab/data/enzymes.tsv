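# Restriction enzyme definitions used by the toolkit.
# Recognition sequences and cut offsets are canonical vendor/REBASE knowledge
# (all sites palindromic; offsets count from the first base of the recognition
# site on the top strand).  cut_top < cut_bottom => 5' extension,
# cut_top > cut_bottom => 3' extension, equal => blunt.
# dam_sensitive marks enzymes whose digestion is blocked by overlapping Dam
# (GATC) methylation in dam+ E. coli hosts; only XbaI matters for the
# BioBrick workflow and only its rule is modelled.
name	recognition	cut_top	cut_bottom	dam_sensitive
EcoRI	GAATTC	1	5	0
NotI	GCGGCCGC	2	6	0
XbaI	TCTAGA	1	5	1
SpeI	ACTAGT	1	5	0
PstI	CTGCAG	5	1	0
NheI	GCTAGC	1	5	0
ClaI	ATCGAT	2	4	0
HindIII	AAGCTT	1	5	0
SmaI	CCCGGG	3	3	0
XhoI	CTCGAG	1	5	0
SacI	GAGCTC	5	1	0
BamHI	GGATCC	1	5	0
SalI	GTCGAC	1	5	0
SphI	GCATGC	5	1	0
ApaI	GGGCCC	5	1	0
BglII	AGATCT	1	5	0
KpnI	GGTACC	5	1	0
AgeI	ACCGGT	1	5	0
BsrGI	TGTACA	1	5	0
StuI	AGGCCT	3	3	0
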