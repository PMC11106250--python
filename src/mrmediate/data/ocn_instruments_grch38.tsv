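SNP	CHR	BP	EA	NEA	EAF	BETA	SE	P	N	F_REPORTED	SOURCE
rs1831272	1	196766611	G	A	0.182	-0.057	0.010	6.71E-09	35667	33.62	ELDJARN
rs185320691	6	32522515	C	G	0.094	0.087	0.013	9.70E-11	35768	41.88	ELDJARN
rs2019727	1	196705584	A	T	0.165	0.107	0.010	4.31E-25	35667	107.06	ELDJARN
rs241430	6	32835043	C	T	0.597	0.050	0.008	1.39E-10	35767	41.18	ELDJARN
rs3132469	6	31488790	G	A	0.810	0.120	0.010	1.29E-34	35768	150.57	ELDJARN
rs3830076	6	32128467	T	C	0.091	0.085	0.013	2.25E-10	35772	40.24	ELDJARN
rs61803031	1	161632464	T	C	0.182	-0.055	0.010	3.37E-08	35689	30.48	ELDJARN
rs76359966	6	32487803	G	T	0.659	0.136	0.007	3.48E-77	35768	345.77	ELDJARN
rs9263708	6	31127493	C	T	0.191	0.084	0.010	8.28E-18	35771	73.88	ELDJARN
rs9273429	6	32659679	A	G	0.562	0.164	0.008	1.18E-99	35768	448.98	ELDJARN
rs3117116	6	32399240	A	G	0.775	0.209	0.023	6.59E-20	5368	84.10	GUDJONSSON
rs35617250	1	196710552	T	C	0.167	0.166	0.026	8.73E-11	5368	42.26	GUDJONSSON
rs71631868	1	196846581	C	T	NA	0.168	0.031	4.27E-08	3301	30.03	SUN
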