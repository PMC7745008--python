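id,sequence
DR001,AGGTTCCAGATGTGTCGCAG
DR002,CTTGTAGGGTCACTATGTCA
DR003,TTTGGAACCGCCAGTTAAAC
DR004,TATTAGAACGGCAGTGAGCT
DR005,GGTTCCAACCTGTGTGGATG
DR006,TTATCCTTACCCCTAAGCGG
DR007,ACCTGCCTGTTCCGTATAAC
DR008,ACATGGCTTTCTAGGTTGTT
DR009,ATATAGGGAGACCCAGAAGC
DR010,GATACGCACGAAGTTCCGCA
DR011,ATAACCTAGTTCAATCGTGG
DR012,AACTGAGCTTGTACACCGTC
DR013,TAAGAGAGGCTGGAACAGTC
DR014,AAAATACGGGATGCAACTAG
DR015,GCTAAGTGCGGACTGAACAT
DR016,GCAGTACGTCTGTTAGGTTC
DR017,TGCCGCTGTACCCAGGTTGA
DR018,GTCTAGCTCATGCGGTAGGA
DR019,ATAAGAAGACTGACCGGTGT
DR020,GCTCCTCCTGAGAACGAGGT
DR021,TTCCAGTGGGTAATGACGTT
DR022,CGCCAGAGAGAGTACAACGA
DR023,ATGAAACGTGATGAATGTGC
DR024,ACTAATCGCCTACTACAACT
DR025,CTCGCGTCTAACAGTGGTTA
DR026,CATTGACGTTCGTGTCGTCG
DR027,TTACCTTGACCGACAACCCT
DR028,ATCGGAGCTAACCCATATGA
DR029,CCGAGTATGTAACCAAAGGC
DR030,TACGAGAATACTAACGCCAT
DR031,CTTAGTCGGCCTTGCTCGAC
DR032,AGTAAATGGGAACAAACGAG
DR033,GCACGCCTACACGTTCCTAT
DR034,ATGAGCGACGATTCGCTGGT
DR035,GGAGAAACACATTCATAGTC
DR036,TTGGCTGCGCCACTAAAAGG
DR037,CTTATCATGCAGGTTATGGA
DR038,GGGTCGAAAGACGATACATA
DR039,CCCGATTAAGGGCTAATTAC
DR040,ATTACGGCAAACCTGCGAAG
DR041,AGGTAACTTATTGGGTTGTC
DR042,CATGGAGCTATGGAAAACAG
DR043,GACTAGTAAGATGGCCGTCT
DR044,CTAGCGCCCTAAGTTGTGTA
DR045,GTGAGCACTCACGCCTAACC
DR046,CAGATTATTCCGCTTCGGCG
DR047,CACTACTCTATGTATCTGTC
DR048,GCCCAACGAATCCAGAACTT
DR049,CGTGTAACTAAGGTGGTCTC
DR050,TAGCGGCACATGATCCGTAA
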