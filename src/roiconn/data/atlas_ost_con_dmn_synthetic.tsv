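label	network	x	y	z
dACC	CON	0	22	32
preSMA	CON	0	10	60
SMA	CON	0	-4	54
FrOperc_L	CON	-40	18	6
FrOperc_R	CON	40	18	6
aIns_L	CON	-36	16	-4
aIns_R	CON	36	16	-4
Precuneus	DMN	0	-62	38
PCC	DMN	0	-50	26
mFrontalPole	DMN	0	58	10
mFrontalGyrus	DMN	0	46	-12
MTL_L	DMN	-26	-22	-18
MTL_R	DMN	26	-22	-18
AngularGyrus_L	DMN	-48	-62	32
AngularGyrus_R	DMN	50	-58	28
OFC_L	OST	-26	34	-14
OFC_R	OST	26	34	-14
dCaudate_L	OST	-13	15	9
dCaudate_R	OST	13	15	9
dPutamen_L	OST	-28	1	3
dPutamen_R	OST	28	1	3
Thalamus_L	OST	-10	-19	6
Thalamus_R	OST	10	-19	6
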