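# Boolean update rules for the 42-node TLR4-mediated early-sepsis network.
# Dialect: & = AND, | = OR, ! = NOT ("&!" = AND NOT, inhibition),
# THR_<node>[<tag>] = <node> active for the last delay(<tag>) consecutive
# steps.  Delays per tag live in the metadata sidecar (tlr4_meta.yaml).
Infection = Infection
Bacteria = Infection &! (Bacteria & (THR_MAC[B_CL] | THR_Phagocytosis[B_CL] | THR_ROS[B_CL] | THR_NETs[B_CL]))
LPS = Bacteria
TLR4 = LPS | (TLR4 & IFN-gamma)
Act-Mon = (TLR4 | IL-1B | (Act-Mon & IFN-gamma)) &! (Act-Mon & (Apoptosis &! IFN-gamma))
Act-Mac = (TLR4 | Act-Mon | C5a | (Act-Mac & (TNF-a | IFN-gamma)) | (IFN-gamma & TNF-a) | (Act-Mon & IL-1B)) &! (Act-Mac & (IL-10 | (Apoptosis &! IFN-gamma)))
Mac-M1 = (Act-Mac & (TNF-a | IFN-gamma)) | (Act-Mon & IL-1B) | (Mac-M2 & (TNF-a | IFN-gamma | IL-1B))
Mac-M2 = (Act-Mac & (IL-10 | IL-1Ra)) | (Mac-M1 & (IL-10 | IL-1Ra))
Act-DC = (TLR4 | Act-Mon) &! (Act-DC & (Treg | IL-10 | Apoptosis))
Act-Neu = (TLR4 | C5a | IL-8) &! (Act-Neu & Apoptosis)
Act-NK = (IL-12 | Act-DC | (Act-NK & (IL-12 & IL-18))) &! (Act-NK & Apoptosis)
Act-EC = (TNF-a | NETs) &! (Act-EC & Apoptosis)
Phagocytosis = (THR_C3b[Phag_L] & THR_Bacteria[Phag_L]) | THR_Act-Mon[Phag_L] | THR_Act-Mac[Phag_L] | THR_Act-Neu[Phag_E] | THR_Act-DC[Phag_L] | (Phagocytosis & IFN-gamma) | (Phagocytosis & IL-18)
Apoptosis = THR_TNF-a[Apop] | THR_Bcell[Apop] | (Apoptosis & LPS)
ICAM-1 = Act-EC | (ICAM-1 & TNF-a)
VCAM-1 = Act-EC | (VCAM-1 & TNF-a)
E-selectin = Act-EC | (E-selectin & ROS)
P-selectin = Act-EC | Act-PLT
NETs = Act-Neu | ROS | (Act-Neu & C5a) | (NETs & Act-PLT)
Act-PLT = LPS | TLR4 | TF | Thrombosis | (Act-PLT & (NETs | IFN-gamma))
TF = THR_Act-Mon[T_TF] | (TF & (THR_Act-EC[T_TF] & (TNF-a | LPS))) | (TF & (THR_Act-Mon[T_TF] & (TNF-a | LPS)))
Thrombosis = NETs & (TF & Act-PLT)
C3b = Bacteria
C5a = C3b
C5b = C3b
MAC = THR_C5b[T_MAC]
ROS = Act-Neu | (Act-Mac | Mac-M1) | Act-EC | (ROS & (TNF-a | IL-18))
Ang2 = Act-EC
TNF-a = (Mac-M1 | Act-Mon | Act-NK | Act-DC | CD4T | CD8T | (TNF-a & (IFN-gamma | Act-Mac | ROS)) | (IL-1B & Act-EC)) &! (TNF-a & ((IL-10 &! IFN-gamma) | sTNF-R))
IL-1B = (Act-Mon | Mac-M1 | (IL-1B & (TNF-a | Act-Mon | Act-PLT))) &! (IL-1B & (IL-10 | IL-1Ra))
IFN-gamma = (Act-NK | (IFN-gamma & (Act-DC & IL-12)) | (Mac-M1 & (IL-12 & IL-18)) | ((CD4T | CD8T) & (IL-12 | (IL-12 & IL-18))) | (IFN-gamma & (CD4T & IL-6))) &! (IFN-gamma & IL-10)
IL-6 = ((Act-Mon & IL-1B) | Mac-M1 | Act-EC | Act-DC | Bcell) &! (IL-6 & IL-10)
IL-8 = (Act-Mon | Mac-M1 | Act-EC | (IL-8 & TNF-a)) &! (IL-8 & IL-10)
IL-12 = (Act-Mon | Mac-M1 | Act-DC | (IL-12 & (Act-NK | IFN-gamma | IL-1B))) &! (IL-12 & IL-10)
IL-18 = (Mac-M1 | Act-DC | Act-EC) &! (IL-18 & IL-10)
IL-10 = (THR_Mac-M2[Anti_inflam] | THR_Act-DC[Anti_inflam] | (THR_CD4T[Anti_inflam] | THR_CD8T[Anti_inflam] | THR_Treg[Anti_inflam] | THR_Bcell[Anti_inflam]) | (IL-10 & (Act-DC | IL-12)) | THR_Apoptosis[Anti_inflam]) &! (IL-10 & IFN-gamma)
sTNF-R = THR_Act-Mon[Anti_inflam] | THR_CD4T[Anti_inflam] | THR_CD8T[Anti_inflam] | (sTNF-R & IL-10)
IL-1Ra = (THR_Act-Neu[Anti_inflam] | THR_Act-Mon[Anti_inflam]) &! (IL-1Ra & IFN-gamma)
CD4T = (Act-DC | IL-6 | (CD4T & (IL-12 | IFN-gamma))) &! (CD4T & (IL-10 | Treg | Apoptosis))
CD8T = (Act-DC | IL-18 | (CD8T & Act-NK)) &! (CD8T & (Treg | IL-10 | Apoptosis))
Treg = (CD4T | (Treg & IL-10)) &! (Treg & (IL-6 | Apoptosis))
Bcell = (TLR4 | (Act-DC & LPS) | (Bcell & IL-6)) &! (Bcell & (Treg | IL-10 | Apoptosis))
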