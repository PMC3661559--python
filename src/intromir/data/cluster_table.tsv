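cluster_members	intron_length	host_gene	intron_ordinal
osa-MIR1862d;osa-MIR1876;osa-MIR1884b	2147	LOC_Os10g08930	2
osa-MIR1423;osa-MIR1868	2470	LOC_Os04g32710	3
osa-MIR1862e;osa-MIR2872	5115	LOC_Os11g05562	3
osa-MIR1863b;osa-MIR1863c	6465	LOC_Os12g09290	1
new-MIR2173;osa-MIR1870;new-MIR2175	2918	LOC_Os06g36160	2
osa-MIR1427;new-MIR2703	8374	LOC_Os08g15204	2
osa-MIR1884a;new-MIR557	1207	LOC_Os02g18660	1
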