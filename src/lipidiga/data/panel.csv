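name,precursor,pathway,unit,lod,compartments
PGE2,AA,COX,pg/mg-protein,0.1,skin;plasma
PGD2,AA,COX,pg/mg-protein,0.2,skin;plasma
PGF2a,AA,COX,pg/mg-protein,0.5,skin;plasma
TXB2,AA,COX,pg/mg-protein,1.0,skin;plasma
6-keto-PGF1a,AA,COX,pg/mg-protein,2.0,skin;plasma
15-deoxy-PGJ2,AA,COX,pg/mg-protein,0.1,skin
PGJ2,AA,COX,pg/mg-protein,0.2,skin
PGB2,AA,COX,pg/mg-protein,0.5,skin
11b-PGF2a,AA,COX,pg/mg-protein,1.0,skin
5-HETE,AA,LOX,pg/mg-protein,2.0,skin;plasma
8-HETE,AA,LOX,pg/mg-protein,0.1,skin;plasma
9-HETE,AA,hybrid-monohydroxy,pg/mg-protein,0.2,skin
11-HETE,AA,hybrid-monohydroxy,pg/mg-protein,0.5,skin;plasma
12-HETE,AA,LOX,pg/mg-protein,1.0,skin;plasma
15-HETE,AA,hybrid-monohydroxy,pg/mg-protein,2.0,skin;plasma
19-HETE,AA,hybrid-monohydroxy,pg/mg-protein,0.1,skin
20-HETE,AA,hybrid-monohydroxy,pg/mg-protein,0.2,skin;plasma
HXA3,AA,LOX,pg/mg-protein,0.5,skin
HXB3,AA,LOX,pg/mg-protein,1.0,skin
LTB4,AA,LOX,pg/mg-protein,2.0,skin;plasma
5-HEPE,EPA,LOX,pg/mg-protein,0.1,skin;plasma
8-HEPE,EPA,LOX,pg/mg-protein,0.2,skin;plasma
9-HEPE,EPA,hybrid-monohydroxy,pg/mg-protein,0.5,skin
11-HEPE,EPA,hybrid-monohydroxy,pg/mg-protein,1.0,skin
12-HEPE,EPA,LOX,pg/mg-protein,2.0,skin;plasma
15-HEPE,EPA,hybrid-monohydroxy,pg/mg-protein,0.1,skin;plasma
18-HEPE,EPA,hybrid-monohydroxy,pg/mg-protein,0.2,skin;plasma
PGE3,EPA,COX,pg/mg-protein,0.5,skin;plasma
PGD3,EPA,COX,pg/mg-protein,1.0,skin
TXB3,EPA,COX,pg/mg-protein,2.0,skin;plasma
LTB5,EPA,LOX,pg/mg-protein,0.1,skin
4-HDHA,DHA,LOX,pg/mg-protein,0.2,skin;plasma
7-HDHA,DHA,LOX,pg/mg-protein,0.5,skin;plasma
8-HDHA,DHA,hybrid-monohydroxy,pg/mg-protein,1.0,skin;plasma
10-HDHA,DHA,hybrid-monohydroxy,pg/mg-protein,2.0,skin
11-HDHA,DHA,hybrid-monohydroxy,pg/mg-protein,0.1,skin;plasma
13-HDHA,DHA,hybrid-monohydroxy,pg/mg-protein,0.2,skin
14-HDHA,DHA,LOX,pg/mg-protein,0.5,skin;plasma
16-HDHA,DHA,hybrid-monohydroxy,pg/mg-protein,1.0,skin
17-HDHA,DHA,LOX,pg/mg-protein,2.0,skin;plasma
20-HDHA,DHA,hybrid-monohydroxy,pg/mg-protein,0.1,skin
9-HODE,LA,hybrid-monohydroxy,pg/mg-protein,0.2,skin;plasma
13-HODE,LA,hybrid-monohydroxy,pg/mg-protein,0.5,skin;plasma
9-oxo-ODE,LA,nonenzymatic,pg/mg-protein,1.0,skin
13-oxo-ODE,LA,nonenzymatic,pg/mg-protein,2.0,skin
t-EKODE,LA,nonenzymatic,pg/mg-protein,0.1,skin;plasma
9-HOTrE,ALA,LOX,pg/mg-protein,0.2,skin;plasma
13-HOTrE,ALA,LOX,pg/mg-protein,0.5,skin;plasma
5-HETrE,DGLA,LOX,pg/mg-protein,1.0,skin
8-HETrE,DGLA,LOX,pg/mg-protein,2.0,skin;plasma
15-HETrE,DGLA,LOX,pg/mg-protein,0.1,skin;plasma
"5,6-EET",AA,CYP450-epoxide,pg/mg-protein,0.2,skin;plasma
"8,9-EET",AA,CYP450-epoxide,pg/mg-protein,0.5,skin;plasma
"11,12-EET",AA,CYP450-epoxide,pg/mg-protein,1.0,skin;plasma
"14,15-EET",AA,CYP450-epoxide,pg/mg-protein,2.0,skin;plasma
"9,10-EpOME",LA,CYP450-epoxide,pg/mg-protein,0.1,skin;plasma
"12,13-EpOME",LA,CYP450-epoxide,pg/mg-protein,0.2,skin;plasma
"14,15-EpETE",EPA,CYP450-epoxide,pg/mg-protein,0.5,skin
"17,18-EpETE",EPA,CYP450-epoxide,pg/mg-protein,1.0,skin;plasma
"7,8-EpDPE",DHA,CYP450-epoxide,pg/mg-protein,2.0,skin
"16,17-EpDPE",DHA,CYP450-epoxide,pg/mg-protein,0.1,skin;plasma
"19,20-EpDPE",DHA,CYP450-epoxide,pg/mg-protein,0.2,skin;plasma
"5,6-DHET",AA,CYP450-diol,pg/mg-protein,0.5,skin;plasma
"8,9-DHET",AA,CYP450-diol,pg/mg-protein,1.0,skin;plasma
"11,12-DHET",AA,CYP450-diol,pg/mg-protein,2.0,skin;plasma
"14,15-DHET",AA,CYP450-diol,pg/mg-protein,0.1,skin;plasma
"9,10-DiHOME",LA,CYP450-diol,pg/mg-protein,0.2,skin;plasma
"12,13-DiHOME",LA,CYP450-diol,pg/mg-protein,0.5,skin;plasma
"14,15-DiHETE",EPA,CYP450-diol,pg/mg-protein,1.0,skin;plasma
"17,18-DiHETE",EPA,CYP450-diol,pg/mg-protein,2.0,skin;plasma
"7,8-DiHDPA",DHA,CYP450-diol,pg/mg-protein,0.1,skin
"19,20-DiHDPA",DHA,CYP450-diol,pg/mg-protein,0.2,skin;plasma
2-AG,AA,eCB,pg/mg-protein,0.5,skin;plasma
1-AG,AA,eCB,pg/mg-protein,1.0,skin
AEA,AA,eCB,pg/mg-protein,2.0,skin;plasma
OEA,saturated/monounsaturated,NAE,pg/mg-protein,0.1,skin;plasma
PEA,saturated/monounsaturated,NAE,pg/mg-protein,0.2,skin;plasma
SEA,saturated/monounsaturated,NAE,pg/mg-protein,0.5,skin;plasma
MEA,saturated/monounsaturated,NAE,pg/mg-protein,1.0,skin;plasma
PDEA,saturated/monounsaturated,NAE,pg/mg-protein,2.0,skin;plasma
HPEA,saturated/monounsaturated,NAE,pg/mg-protein,0.1,skin;plasma
PLEA,saturated/monounsaturated,NAE,pg/mg-protein,0.2,skin;plasma
LEA,LA,NAE,pg/mg-protein,0.5,skin;plasma
ALEA,ALA,NAE,pg/mg-protein,1.0,skin;plasma
DGLEA,DGLA,NAE,pg/mg-protein,2.0,skin;plasma
DPEA,other,NAE,pg/mg-protein,0.1,skin;plasma
DHEA,DHA,NAE,pg/mg-protein,0.2,skin;plasma
EPEA,EPA,NAE,pg/mg-protein,0.5,skin;plasma
8-iso-PGF2a,AA,nonenzymatic,pg/mg-protein,1.0,skin;plasma
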