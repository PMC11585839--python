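gene	cluster_id	arm	weight
APOL6	APOL6	M1	-1.0
LIMK2	LIMK2	M1	-1.0
IL15	IL15	M1	-1.0
CLK2	CLK2	M2	1.0
CRTAP	CRTAP	M2	1.0
DFFB	DFFB	M2	1.0
EEF1B2	EEF1B2	M2	1.0
MGAT4A	MGAT4A	M2	1.0
RPL14	RPL14	M2	1.0
RPL15	RPL15	M2	1.0
RPL17	RPL17	M2	1.0
RPL24	RPL24	M2	1.0
RPL35A	RPL35A	M2	1.0
RPL9	RPL9	M2	1.0
RPS15A	RPS15A	M2	1.0
RPS16	RPS16	M2	1.0
TTC31	TTC31	M2	1.0
ZNF266	ZNF266	M2	1.0
MFNG	MFNG	M2	1.0
MKKS	MKKS	M2	1.0
NDUFB8	NDUFB8	M2	1.0
PAN2	PAN2	M2	1.0
SLC26A6	SLC26A6	M2	1.0
ZNF133	ZNF133	M2	1.0
ZNF589	ZNF589	M2	1.0
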