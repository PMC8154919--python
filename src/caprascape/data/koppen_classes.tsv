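breed_code	current_class	future_class
GAR	BSk	BSk
MNT_I	BSk	Csa
MON	Cfa	BSk
NVE	Cfa	Cfa
ALP	Cfa	Csa
FAC	Cfa	Csa
FUL	Cfb	Csa
DDS	Csa	BSh
GIR	Csa	BSh
MAL	Csa	BSh
ASP	Csa	Csa
BIA	Csa	Csa
CAP	Csa	Csa
GRF	Csa	Csa
MES	Csa	Csa
NIC	Csa	Csa
RCC	Csa	Csa
RME	Csa	Csa
SAR	Csa	Csa
ARG	Csb	Csa
GCI	Csb	Csa
JON	Csb	Csa
SAM	Csb	Csa
BIO	Dfb	Cfa
SAA	Dfb	Cfa
VLS	Dfb	Cfa
TER	Dfb	Csa
MNT_M	Dfb	Csb
LIV	Dfc	Dfb
ORO	Dfc	Dfb
VPS	Dfc	Dfb
VAL	EF	Dfb
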