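nest_id	complex	n_offspring	observed_mother	inferred_mother	probability
Apua-01	Apua	19	153	153	1.000
Apua-02	Apua	46	153	153	1.000
Apua-03	Apua	4	155	155	1.000
Apua-06	Apua	25	153	153	1.000
Apua-07	Apua	21	none	153	1.000
Apua-08	Apua	62	158	158	1.000
Apua-09	Apua	51	154	154	1.000
Apua-10	Apua	4	155	155	1.000
Apua-11	Apua	16	153	153	1.000
Apua-12	Apua	16	none	158	1.000
Apua-14	Apua	37	155	155	1.000
Apua-15	Apua	95	none	158	1.000
Apua-16	Apua	21	none	158	1.000
Halape-01	Apua	72	none	85	1.000
Halape-02	Apua	10	85	85	1.000
Halape-03	Apua	76	85	85	1.000
Pohue-01	Pohue	4	none	119	0.991
Pohue-02	Pohue	1	151	151	1.000
Pohue-03	Pohue	19	152	152	1.000
Pohue-04	Pohue	2	119	119	0.991
Pohue-05	Pohue	9	71	71	1.000
Pohue-06	Pohue	30	76	76	1.000
Pohue-07	Pohue	8	151	151	1.000
Pohue-08	Pohue	6	152	152	1.000
Pohue-09	Pohue	8	none	157	1.000
Pohue-10	Pohue	14	119	119	0.991
Pohue-11	Pohue	48	76	76	1.000
Pohue-12	Pohue	15	71	71	1.000
Pohue-13	Pohue	1	151	151	1.000
Pohue-15	Pohue	18	152	152	1.000
Pohue-17	Pohue	17	71	71	1.000
Pohue-18	Pohue	8	151	151	1.000
Pohue-19	Pohue	20	76	76	1.000
Pohue-20	Pohue	23	none	76	1.000
Pohue-21	Pohue	7	152	152	1.000
Pohue-24	Pohue	8	none	159*	0.687
Pohue-25	Pohue	3	160	159*	0.687
Awili-01	Pohue	54	none	157	1.000
Awili-02	Pohue	59	none	157	1.000
Koloa-01	Kamehame	10	none	110	1.000
Koloa-02	Kamehame	23	none	110	1.000
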