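female	beaches	n_nests	n_offspring	mean_per_nest	mate	mate_r
153	Apua	5	162	32.4	P01	0.25
154	Apua	1	55	55	P04	0.15
155	Apua	3	58	19.3	P02	0.14
158	Apua	4	238	59.5	P03	0.24
85	Halape	3	168	56	P06	0.28
119	Pohue	3	31	10.3	P07	0.27
151	Pohue	4	33	8.25	P09	-0.06
152	Pohue	4	83	20.7	P10	-0.05
157	Awili;Pohue	3	127	42.3	P05	0.09
71	Pohue	3	49	16.3	P11	0.07
76	Pohue	4	138	34.5	P07	0.07
110	Koloa	2	44	22	P8	0.27
160/159	Pohue	2	30	10	P12	-0.04
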