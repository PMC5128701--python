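otu	accession	count	family	genus	best_match_identity_pct
PA-30	LN865035	20	Halobacteriaceae	Halanaeroarchaeum	94
PA-73	LN865045	5	Halobacteriaceae	Halanaeroarchaeum	98
PA-105	LN865050	4	Halobacteriaceae	Halanaeroarchaeum	93
PA-21	LN865033	1	Halobacteriaceae	Halanaeroarchaeum	96
PA-2	LN865027	17	Halobacteriaceae	Halorubrum	98
PA-103	LN865049	4	Halobacteriaceae	Halorubrum	98
PA-53	LN865040	3	Halobacteriaceae	Halorubrum	99
PA-52	LN865039	1	Halobacteriaceae	Halorubrum	94
PA-3	LN865028	17	Halobacteriaceae	Halonotius	98
PA-61	LN865043	1	Halobacteriaceae	Halonotius	98
PA-8	LN865029	7	Halobacteriaceae	Halovenus	97
PA-51	LN865038	3	Halobacteriaceae	Natronomonas	93
PA-139	LN865052	1	Halobacteriaceae	Natronomonas	93
PA-11	LN865031	2	Halobacteriaceae	Salinigranum	99
PA-54	LN865041	1	Halobacteriaceae	Salinigranum	98
PA-79	LN865046	2	Halobacteriaceae	Halomicrobium	93
PA-63	LN865044	2	Halobacteriaceae	Halogeometricum	93
PA-57	LN865042	2	Halobacteriaceae	Haloarchaeobius	98
PA-33	LN865036	2	Halobacteriaceae	Salinirubrum	99
PA-87	LN865048	1	Halobacteriaceae	Haloarcula	99
PA-17	LN865032	1	Halobacteriaceae	Haloquadratum	96
PA-145	LN865053	1	Halobacteriaceae	Halorhabdus	94
PA-89	LN865030	7	Haloferaceae	Halobellus	96
PA-80	LN865047	1	Haloferaceae	Haloferax	90
PA-26	LN865034	2	Unclassified	Unclassified	95
PA-112	LN865051	1	Unclassified	Unclassified	95
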