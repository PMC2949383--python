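observed_kb	insilico_kb	chrom	start	end
10.80	10.733	2R	14258754	14259758
10.61	10.994	2R	3123723	3125343
9.40	9.423	X	21967238	21968858
9.05	9.042	2R	13037805	13039425
7.05	7.116	3R	25479232	25480852
5.35	5.379	3R	4533548	4630591
4.85	4.860	3R	2336147	2337767
4.60	4.579	3L	26306697	26308317
4.26	4.300	2R	14249021	14249636
4.24	4.252	2L	4921270	4922890
4.15	4.047	3L	9572121	9573741
ND	4.005	3R	24079459	24081079
3.20	3.208	2R	6910509	6912129
2.84	2.860	3R	24618986	24620606
2.75	2.772	X	1412540	1414160
2.40	2.389	2L	20894671	20896291
2.31	ND	ND	ND	ND
2.11	ND	ND	ND	ND
2.05	2.044	2L	47862	49482
ND	1.992	2R	8707349	8708969
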