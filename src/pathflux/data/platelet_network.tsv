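# Curated directed platelet-aggregation pathway network (synthetic curation:
# a best-effort 64-node/91-edge approximation assembled from public pathway
# knowledge; node and edge counts are the curation constraint).
# Format: %node <id> <kind> [label]; %exit <id>; edges source<TAB>target.
%node AC protein Adenylate cyclase
%node GPIIbIIIa protein Glycoprotein IIb/IIIa complex
%node IP3R protein Inositol 1,4,5-trisphosphate receptor
%node P2X1 protein P2X purinoceptor 1
%node P2Y1 protein P2Y purinoceptor 1
%node P2Y12 protein P2Y purinoceptor 12
%node PAR1 protein Proteinase-activated receptor 1
%node PAR4 protein Proteinase-activated receptor 4
%node PI3K protein Phosphatidylinositol 3-kinase
%node Akt protein RAC-alpha serine/threonine-protein kinase
%node PKC protein Protein kinase C
%node PLA2 protein Phospholipase A2
%node PLCB2 protein Phosphoinositide phospholipase C beta-2
%node PLCG2 protein Phosphoinositide phospholipase C gamma-2
%node COX1 protein Prostaglandin G/H synthase 1
%node Rap1b protein Ras-related protein Rap-1b
%node Thrombin protein Thrombin
%node TXA2Ra protein Thromboxane A2 receptor alpha
%node TXA2Rb protein Thromboxane A2 receptor beta
%node GPVI protein GPVI
%node FcRgamma protein FcRgamma
%node GPIb protein GPIb
%node vWF protein vWF
%node Syk protein Syk
%node LAT protein LAT
%node SLP76 protein SLP76
%node Btk protein Btk
%node Gq protein Gq
%node Gi protein Gi
%node G12 protein G12
%node Gs protein Gs
%node RhoA protein RhoA
%node ROCK protein ROCK
%node MLCK protein MLCK
%node MLC protein MLC
%node CalDAGGEF1 protein CalDAGGEF1
%node RIAM protein RIAM
%node Talin protein Talin
%node TXAS protein TXAS
%node PKA protein PKA
%node VASP protein VASP
%node Src protein Src
%node Fyn protein Fyn
%node HTR2A protein HTR2A
%node PDE3 protein PDE3
%node STIM1 protein STIM1
%node Orai1 protein Orai1
%node Collagen protein Collagen
%node Fibrinogen protein Fibrinogen
%node ADP small_molecule ADP
%node ATP small_molecule ATP
%node TXA2 small_molecule TXA2
%node AA small_molecule Arachidonic acid
%node PGH2 small_molecule PGH2
%node IP3 small_molecule IP3
%node DAG small_molecule DAG
%node PIP2 small_molecule PIP2
%node PIP3 small_molecule PIP3
%node Ca small_molecule Calcium ion
%node cAMP small_molecule cAMP
%node Serotonin small_molecule Serotonin (5-HT)
%node Aggregation event Platelet aggregation
%node ShapeChange event ShapeChange
%node GranuleSecretion event GranuleSecretion
%exit Aggregation
Collagen	GPVI
Collagen	vWF
vWF	GPIb
Thrombin	PAR1
Thrombin	PAR4
Thrombin	GPIb
ADP	P2Y1
ADP	P2Y12
ATP	P2X1
TXA2	TXA2Ra
TXA2	TXA2Rb
Serotonin	HTR2A
GPVI	FcRgamma
GPVI	Fyn
Fyn	FcRgamma
FcRgamma	Syk
Syk	LAT
LAT	SLP76
LAT	PI3K
SLP76	Btk
Btk	PLCG2
Syk	PLCG2
GPIb	Src
Src	Syk
GPIb	PI3K
PAR1	Gq
PAR1	G12
PAR4	Gq
PAR4	G12
P2Y1	Gq
P2Y12	Gi
TXA2Ra	Gq
TXA2Rb	G12
HTR2A	Gq
Gq	PLCB2
G12	RhoA
Gi	AC
Gi	PI3K
Gs	AC
RhoA	ROCK
ROCK	MLC
MLCK	MLC
MLC	ShapeChange
ShapeChange	Aggregation
PIP2	PLCB2
PIP2	PLCG2
PIP2	PI3K
PLCB2	IP3
PLCB2	DAG
PLCG2	IP3
PLCG2	DAG
IP3	IP3R
IP3R	Ca
IP3R	STIM1
STIM1	Orai1
Orai1	Ca
P2X1	Ca
Ca	MLCK
Ca	PKC
Ca	CalDAGGEF1
Ca	PLA2
DAG	PKC
DAG	CalDAGGEF1
PKC	GranuleSecretion
GranuleSecretion	ADP
GranuleSecretion	ATP
GranuleSecretion	Serotonin
GranuleSecretion	Aggregation
PLA2	AA
AA	COX1
COX1	PGH2
PGH2	TXAS
TXAS	TXA2
PI3K	PIP3
PIP3	Akt
PIP3	Btk
Akt	Rap1b
Akt	PDE3
PDE3	cAMP
CalDAGGEF1	Rap1b
Rap1b	RIAM
RIAM	Talin
Talin	GPIIbIIIa
Fibrinogen	GPIIbIIIa
GPIIbIIIa	Aggregation
GPIIbIIIa	Src
AC	cAMP
cAMP	PKA
PKA	VASP
PKA	IP3R
VASP	GPIIbIIIa
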