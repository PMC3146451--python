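>ssrA_synthetic 353 nt synthetic tmRNA gene; 3' 20 bp tag
TGTCGCTGCCTAAAGCCACGCGATTGGCGGGTTGTAGGCCCATCTCACAGGCGTACCTAGCTGGAAGTCA
TCATTACCCCTATACCGTCTTTCAGCCTTCATGTCAACCACAACCGCGTGCCGAGCCGGCTTTAGCCTTA
GCCTAGGAAAATTCCCAGGTCCAACAAATGAGTTCTGCATAATCGAAGATCGGTGCCTCAATACCATAAA
GCCTCAGCATGCTCGCATGTACTCTCCTCGTACTACTAATCGACGATACCTGCGGGTAAATATGGACAGA
GGTGATAGCGGAGCCGAACCCGTCCGGTTCCTACACATCGTACACATGGCTGGTTTGTCCAGATATGCGC
GAG
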