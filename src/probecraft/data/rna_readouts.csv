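id,sequence
RR001,GTGCGTGGGATCAAACTCTA
RR002,TCGCTAGTGAAACGTCAATA
RR003,GCTTAATCAGGCATAAAGGT
RR004,ACTTCTTCCGATGTAATCCA
RR005,TTGAGCGACGTAGTCGTTAT
RR006,TAGCCAAGTGGATACCCAGC
RR007,AGAGGTGAAGTACGGCTACT
RR008,CGTCAGGAGGGAAAATATAT
RR009,CTATTTGAAATGTGACGCCC
RR010,CGATAGAGGTCTGTAATCAG
RR011,CACGGATCTAGCTGACCTCA
RR012,AGCGCACAGAACCATGTGAC
RR013,AACGTCTCCAGGCGTGCTTA
RR014,ATCCGGTTACTCTGTTCGGG
RR015,CCAAGAATGGCCATCTCGGG
RR016,TCATGTGCGAGGAGATTGTA
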