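species	group	HBII-436	HBII-13	HBII-438A	HBII-85	HBII-52	HBII-438B
Human	primates	1	1	1	27	41	1
Chimp	primates	1	1	1	22	44	1
Rhesus	primates	1	1	1	28	58	1
Rat	rodents	1	1	0	24	39	0
Mouse	rodents	1	1	0	27	130	0
Dog	other	1	0	1	9	4	1
Cat	other	1	2	0	6	20	0
Horse	other	1	0	1	12	2	1
Cow	other	0	0	0	8	0	1
Armadillo	other	1	2	0	9	0	1
Tenrec	other	0	0	0	0	0	0
Elephant	other	0	1	0	1	70	1
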