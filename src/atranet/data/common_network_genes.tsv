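role	gene
regulator	ESRRG
regulator	FOSL2
regulator	FOXJ3
regulator	HOXD1
regulator	MEIS2
regulator	KLF11
regulator	NFE2L2
regulator	NFIB
regulator	PRDM2
regulator	STAT5A
target	NFASC
target	LGALS12
target	TM7SF2
target	CRB1
target	PRCD
target	STAT5A
target	LGI1
target	ALS2CR8
target	SNAP25
target	ZNF189
target	CFLAR
target	GABARAPL1
target	ANKRD6
target	ADD3
target	CREBRF
target	ZBTB18
target	L3MBTL1
target	HBP1
target	DNAH9
target	GARNL3
target	RGS18
target	CREBL2
target	YPEL2
target	OGFOD1
target	DPP6
target	NTRK2
target	SCN2A
target	ZSCAN26
target	CDKN2AIP
target	ARHGEF7
target	CHEK1
target	RUFY3
target	BCL2
target	KLF11
target	ATP6AP1L
target	RRAGB
target	PRDM2
target	BAI3
target	CCDC146
target	SYN2
target	PELO
target	KIAA1377
target	RHBDL1
target	GNG3
target	ZNF211
target	ARPC4-TTLL3
target	ZCCHC12
target	SLC25A27
target	RGS13
target	CLIP3
target	RASL10B
target	C4orf6
target	RUNDC3B
target	PURG
target	MMP11
target	TGM2
target	ATP2B3
target	SLC35D3
target	TTLL3
target	RAB26
target	ZNF555
target	CACNA1B
target	LINC00086
target	ZFP2
target	ATP7A
target	ATRNL1
target	ZNF625
target	BBS9
target	PCBP1-AS1
target	CNTN2
target	RFPL1S
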