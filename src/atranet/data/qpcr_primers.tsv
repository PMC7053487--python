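gene	role	forward	reverse
BCL2	projection	TTGGCCCCCGTTGCTTTTCCTC	TCCCACTCGTAGCCCCTCTGCGAC
DNAH9	projection	GAACTTGGAGAGGTGTGCCT	GGCCCTTGTGGTTTGTTTCTC
BBS9	projection	ACCGATGTTGAGGTGGGAAC	GGATAACTCGCGGAATGCCA
TTLL3	projection	TGATCCACGCACTTCAGACC	GAGCCGGATGCCCACATATT
CRB1	projection	CCAGCAACACACCAGAGGAT	TTGAGAGGCACCTGGTGTTG
TM7SF2	projection	CTGCCTCATCAATGGGCTTG	GATAGTTGGGATGGCGGACC
RHBDL1	projection	CTCATCCAGGAGCAGCAG	TAGCAATGGCCCGCTTGAA
SCN2A	projection	GCTTCCGCTTCTTTACCAGG	GCGTTCCTGTTTGGGTCTCT
NTRK2	projection	CAATTGTGGTTTGCCATCTG	TGCAAAATGCACAGTGAGGT
NFASC	projection	CGAGCCCTTGGAGGTTGATT	AGACTGAGGAGGCAGAGGAG
CNTN2	projection	CACACCTCACCATCCTTCAGTC	CACATTTATCCTCTGCCCTTCC
SNAP25	projection	GAACACAACCCTCCCGAGAA	GTTCATGCCTTCTTCGACACG
RUFY3	projection	GAAAGTTTCGGTTCTGCCCG	TATGCAAGCTGGTGCTGTCA
MAP2	marker	CAGTTTGGCTGAAGGTAGCTGAA	CACATCTGTGTGAGTGTGTGTGTGGA
SYN1	marker	TGACCAATGCCTTCAACCTTC	AGTGGGGTATCAGTCGGAGAA
SYP	marker	AGGTGCTGCAATGGGACTTT	GTTGAGTCCCGAGGTCACAG
ATP7A	projection	TGGCAAGGCAGAAGTAAGGTATAA	ACGTCATTCCCCTCACAACAAG
ARHGEF7	projection	GCCTGGATAAATACCCTACGC	GGATGGCTTCCGTCAGGAT
ACTB	cytoskeletal	AGGCCAACCGCGAGAAGATGACC	GAAGTCCAGGGCGACGTAGCAC
GAPDH	reference	TTCTTTTGCGTCGCCAGCCGA	GTGACCAGGCGCCCAATACGA
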