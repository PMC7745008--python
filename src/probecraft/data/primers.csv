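probe_type,forward,reverse
chromatin,ATCACGGCGGCTGGATATAG,GATCGCTCCCCTCATTAAAG
merfish,AGTGACGCTGCACATTATAT,AGCATTTAGGTCATACGCTT
smfish,AAAATCAGCACACAACGGGG,AGTCGTTGCGTGCGAGTCAT
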