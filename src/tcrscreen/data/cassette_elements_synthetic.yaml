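# Synthetic stand-ins for the expression-cassette elements
# (leaders, constant-region remainder); P2A is the canonical
# teschovirus-derived ribosomal-skip sequence.
leader_length: 48
beta_leader_mod: ATGGAGGCCGATCCGAGACCACGCCAGTCGGTCGTCTGGACCCGGCAC
alpha_leader_mod: ATGTTCTGGCTCAGCCACTTCTCATTCGTCGGAACGCGTGGGGCCAAG
cbeta_rest: CGCCTGACGCCACGGCCGGAGCATTCCTATACTCATCAGTCGTCGGCCACGCAACAGCGCTCGGCAGAGGAATACAACTCTCCGTCCTAC
p2a: GGAAGCGGAGCTACTAACTTCAGCCTGCTGAAGCAGGCTGGAGACGTGGAGGAGAACCCTGGACCT
default_linker: ACTAGTCCCAGAGTTTTCCTCGGCACGCGT
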