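# Example degron motif definitions (ELM-style consensus subset).
# Curated motif collections are supplied by the user in this same format.
motif_name	e3_ligase	pattern
APC_DBox	APC/C	RxxLxx[LIVM]
APC_KEN	APC/C	KEN
SCF_TRCP	SCF-betaTrCP	DSGx{2,4}[ST]
SCF_FBW7	SCF-FBW7	[LIVMP]x[ST]Pxx[ST]
CBL_PTK	CBL	[DN]x[LIVM]Yxx[LIVMP]
MDM2_SWFB	MDM2	[FW]xx[LIVMW]W
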