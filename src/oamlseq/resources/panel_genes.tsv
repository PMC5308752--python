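gene	pathway
BCL10	NF-kB canonical
BIRC3	NF-kB canonical and non-canonical
CARD11	NF-kB canonical
CD79A	NF-kB canonical
CD79B	NF-kB canonical
CYLD	NF-kB canonical and non-canonical
FAS	Extrinsic apoptosis
IKBKG	NF-kB canonical
KMT2D	Methylation
MALT1	NF-kB canonical
MAP3K7	NF-kB canonical
MAP3K14	NF-kB non-canonical
MYD88	NF-kB canonical
NFKBIA	NF-kB canonical
NOTCH1	Notch
NOTCH2	Notch
RIPK1	NF-kB canonical
RIPK2	NF-kB canonical
TNFAIP3	NF-kB canonical
TNIP1	NF-kB canonical
TNIP2	NF-kB canonical
TP53	Extrinsic apoptosis
TRAF3	NF-kB non-canonical
TRAF6	NF-kB canonical
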