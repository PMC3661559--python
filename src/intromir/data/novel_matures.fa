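>miR53 precursor=MIR53
UUAUAUUUUGGGAUGAAGUGA
>miR263 precursor=MIR263
GUGGGUCUAAGGACUAUAUUAACC
>miR557 precursor=MIR557
AUUUGUUGUAUUAGGGAAUGUCUC
>miR851 precursor=MIR851
AACGGCAAUGGCAUUUCUCGG
>miR966 precursor=MIR966
AUGACUUACAAUCUGAAACGGA
>miR1188 precursor=MIR1188
UGGAUGUGACAUACUCUAGUA
>miR1414 precursor=MIR1414
AGCUUCUGACAGCUGCAGUUUCUC
>miR2745 precursor=MIR2745
UUUGGACCGGUAUGAUACAAUAAA
>miR2749 precursor=MIR2749
AACCUAGUACUGAAUGUGACGCAU
>miR2661 precursor=MIR2661
AGGCUGUAGGAUUUGGGUUGAACC
>miR1181 precursor=MIR1181
AAACUUUCCUGGUCGCGUCGG
>miR2944.1 precursor=MIR2944
AGUGACGAGUAUGAAGAGUUGAAG
>miR2944.2 precursor=MIR2944
AUGGUAAGGAAAGGUAGCAGUAGC
>miR2944.3 precursor=MIR2944
AAGAGUUGAAGAAGAAUGUGAUGG
>miR2173.1 precursor=MIR2173
UAGAGACAAUAAGAGAUCGGG
>miR2173.2 precursor=MIR2173
UAUGAUAGAGACAAUAAGAGA
>miR2173.3 precursor=MIR2173
UGAUAGAGACAAUAAGAGAUCGGG
>miR1004.1 precursor=MIR1004
AGGGUAUUUUGGUAUUUUCCUGUC
>miR1004.2 precursor=MIR1004
AAUAUAUUUUGUACAAGAGAUGGG
>miR2687.1 precursor=MIR2687
AGAAACGGCACUUGUGAAAUCCAA
>miR2687.2 precursor=MIR2687
UGAGAAACGGCACUUGUGAAAUCC
>miR913.1 precursor=MIR913
AUGGUACUGUAACCAGAAGCGG
>miR913.2 precursor=MIR913
UGGUACUGUAACCAGAAGCGGGC
>miR913.3 precursor=MIR913
UCCGGCUACAGUACCAUACUAC
>miR1234.1 precursor=MIR1234
AUAGUUUGUGGUUCAAGUCGCAGA
>miR1234.2 precursor=MIR1234
UAACUGCAUAUAUUUUGGUAU
>miR1234.3 precursor=MIR1234
ACUAAAACAUAUGUAGUUAAGUGC
>miR1234.4 precursor=MIR1234
UGUAGUUAAGUGCCAGGUGUC
>miR2703.1 precursor=MIR2703
AGACCGCGCGGUAUCGCGCAACGA
>miR2703.2 precursor=MIR2703
AUUGUGCGAGACUGUUCAGUUUCG
>miR2703.3 precursor=MIR2703
UUUAUUGUGCGAGACUGUUCAGUU
>miR2703.4 precursor=MIR2703
GUCUCGCAUAAUGAGUGAGCGAGA
>miR2061.1 precursor=MIR2061
GAGGACAGGUGGGAUGGGAUGAUC
>miR2061.2 precursor=MIR2061
AAACCAAACACCUUGAAAAAUGGG
>miR2061.3 precursor=MIR2061
UGUUUGGUUUGAGGACAGGUGGGA
>miR2061.4 precursor=MIR2061
AGGGUGUUUGGUUUGAGGACAGGU
>miR2175.1 precursor=MIR2175
AAAGUCAAAACGGCUUAUAAUUUG
>miR2175.1* precursor=MIR2175
UAUUAUAAGACGUUUUGACUUUUU
>miR2175.2 precursor=MIR2175
UCAAAACGGCUUAUAAUUUGAAAC
>miR2175.3 precursor=MIR2175
AAACGGCUUAUAAUUUGAAACAGA
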