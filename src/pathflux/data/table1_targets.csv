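target,name,uniprot,pdb,reference_ligand,score
AC,Adenylate cyclase,O60266,1AB8,1AB8,6.38
GPIIbIIIa,Glycoprotein IIb/IIIa complex,P05106,2VDM,2VDM,5.29
IP3R,"Inositol 1,4,5-trisphosphate receptor",Q14643,1N4K,1N4K,9.14
P2X1,P2X purinoceptor 1,P51575,4DW1,4DW1,5.20
P2Y1,P2Y purinoceptor 1,P47900,1Y36,AMP,5.38
P2Y12,P2Y purinoceptor 12,Q9H244,1T78,AMP,3.84
PAR1,Proteinase-activated receptor 1,P25116,Model,F16357,5.38
PAR4,Proteinase-activated receptor 4,Q96RI0,Model,YD3,4.28
PI3K,Phosphatidylinositol 3-kinase,P48736,4FUL,4FUL,6.78
Akt,RAC-alpha serine/threonine-protein kinase,P31751,3D0E,3D0E,5.39
PKC,Protein kinase C,P17252,3IW4,3IW4,6.89
PLA2,Phospholipase A2,P14555,1J1A,1J1A,5.22
PLCB2,Phosphoinositide phospholipase C beta-2,Q00722,2ZKM,U73122,5.62
PLCG2,Phosphoinositide phospholipase C gamma-2,P16885,2W2W,U73122,5.00
COX1,Prostaglandin G/H synthase 1,P23219,3N8X,3N8X,5.05
Rap1b,Ras-related protein,Q9H0U4,3NKV,3NKV,5.30
Thrombin,Thrombin,P00734,3DUX,3DUX,5.02
TXA2Ra,Thromboxane A2 receptor alpha,P21731,1LBN,SQ29548,7.90
TXA2Rb,Thromboxane A2 receptor beta,P21731,1LBN,SQ29548,7.90
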