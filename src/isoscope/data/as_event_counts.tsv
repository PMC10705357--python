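# Published alternative-splicing event counts by category (same study)
type	count
SKIP	22174
MSKIP	7520
IR	5066
MIR	1654
AE	8147
XSKIP	18564
XMSKIP	19034
XIR	8332
XMIR	858
XAE	10276
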