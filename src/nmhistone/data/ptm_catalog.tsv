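family	position	residue	mark_label	category
H3	2	R	H3R2me2	activation_repression
H3	3	T	H3T3ph	mitosis_phospho
H3	4	K	H3K4me3	promoter
H3	6	T	H3T6ph	activation_repression
H3	9	K	H3K9me3	heterochromatin
H3	10	S	H3S10ph	mitosis_phospho
H3	14	K	H3K14ac	activation_repression
H3	18	K	H3K18ac	activation_repression
H3	23	K	H3K23ac	activation_repression
H3	27	K	H3K27me3	heterochromatin
H3	28	S	H3S28ph	mitosis_phospho
H3	36	K	H3K36me3	elongation
H3	56	K	H3K56ac	activation_repression
H3	64	K	H3K64me3	heterochromatin
H3	79	K	H3K79me3	elongation
H4	1	S	H4S1ph	mitosis_phospho
H4	3	R	H4R3me2	activation_repression
H4	5	K	H4K5ac	activation_repression
H4	8	K	H4K8ac	activation_repression
H4	12	K	H4K12ac	activation_repression
H4	16	K	H4K16ac	activation_repression
H4	20	K	H4K20me3	heterochromatin
H4	31	K	H4K31ac	activation_repression
H4	91	K	H4K91ac	activation_repression
H2B	5	K	H2BK5ac	activation_repression
H2B	12	K	H2BK12ac	activation_repression
H2B	15	K	H2BK15ac	activation_repression
H2B	20	K	H2BK20ac	activation_repression
H2B	120	K	H2BK120ub1	elongation
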