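# 96-gene cardiac cardiomyopathy/arrhythmia panel: molecular function /
# subcellular-association category per gene (curated from gene-function
# databases; one category per gene).
gene	category
TTN	sarcomere
MYH7	sarcomere
MYH6	sarcomere
MYBPC3	sarcomere
TNNT2	sarcomere
TNNI3	sarcomere
TNNC1	sarcomere
TPM1	sarcomere
ACTC1	sarcomere
MYL2	sarcomere
MYL3	sarcomere
MYL4	sarcomere
MYPN	sarcomere
MYOZ2	sarcomere
TCAP	sarcomere
CSRP3	sarcomere
ANKRD1	sarcomere
ACTN2	sarcomere
NEXN	sarcomere
NEB	sarcomere
DES	cytoskeleton
DMD	cytoskeleton
VCL	cytoskeleton
LDB3	cytoskeleton
FLNC	cytoskeleton
CRYAB	cytoskeleton
BAG3	cytoskeleton
DTNA	cytoskeleton
ILK	cytoskeleton
PDLIM3	cytoskeleton
NEBL	cytoskeleton
SYNM	cytoskeleton
SPEG	cytoskeleton
LAMA2	cell_membrane
LAMA4	cell_membrane
CAV3	cell_membrane
SGCD	cell_membrane
SGCB	cell_membrane
SNTA1	cell_membrane
FKTN	cell_membrane
ITGA7	cell_membrane
DSP	intercalated_disc
DSG2	intercalated_disc
DSC2	intercalated_disc
PKP2	intercalated_disc
JUP	intercalated_disc
CTNNA3	intercalated_disc
GJA1	intercalated_disc
GJA5	intercalated_disc
SCN5A	ion_flux
SCN1B	ion_flux
SCN2B	ion_flux
SCN3B	ion_flux
SCN4B	ion_flux
KCNQ1	ion_flux
KCNH2	ion_flux
KCNE1	ion_flux
KCNE2	ion_flux
KCNE3	ion_flux
KCNJ2	ion_flux
KCNJ5	ion_flux
KCNJ8	ion_flux
KCND3	ion_flux
KCNA5	ion_flux
HCN4	ion_flux
RYR2	ion_flux
CASQ2	ion_flux
TRDN	ion_flux
CALM1	ion_flux
CALM2	ion_flux
CALM3	ion_flux
CACNA1C	ion_flux
CACNB2	ion_flux
CACNA2D1	ion_flux
ANK2	ion_flux
AKAP9	ion_flux
GAA	metabolism
PRKAG2	metabolism
TAZ	metabolism
ABCC9	metabolism
GLA	metabolism
LAMP2	metabolism
AGL	metabolism
DOLK	metabolism
SLC22A5	metabolism
CPT2	metabolism
LMNA	nucleus
EMD	nucleus
RBM20	nucleus
EYA4	nucleus
TBX5	nucleus
TBX20	nucleus
NKX2-5	nucleus
GATA4	nucleus
GATA6	nucleus
PRDM16	nucleus
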