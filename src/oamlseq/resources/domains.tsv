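gene	domain	aa_start	aa_end
NOTCH1	EGF	20	1426
NOTCH1	LNR	1449	1563
NOTCH1	HD-N	1571	1679
NOTCH1	HD-C	1680	1735
NOTCH1	TM	1736	1756
NOTCH1	RAM	1763	1848
NOTCH1	ANK	1927	2093
NOTCH1	NLS	2105	2140
NOTCH1	TAD	2194	2398
NOTCH1	PEST	2480	2555
NOTCH2	EGF	26	1372
NOTCH2	LNR	1378	1491
NOTCH2	HD-N	1500	1605
NOTCH2	HD-C	1606	1672
NOTCH2	TM	1677	1697
NOTCH2	RAM	1705	1790
NOTCH2	ANK	1828	1994
NOTCH2	TAD	2100	2300
NOTCH2	PEST	2400	2471
KMT2D	PHD	150	350
KMT2D	HMG	2030	2100
KMT2D	NLS	3560	3580
KMT2D	FYRN	4995	5048
KMT2D	FYRC	5242	5298
KMT2D	SET	5397	5513
TNFAIP3	ZNF	381	405
TNFAIP3	ZNF	472	496
TNFAIP3	ZNF	514	538
TNFAIP3	ZNF	587	611
TNFAIP3	ZNF	639	663
TNFAIP3	ZNF	685	709
TNFAIP3	ZNF	755	779
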