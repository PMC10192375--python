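>TRBV15-1
ATGCGCATGGTCATCAATGATGGTCCTGGTACCTGCTGCTCCTTAAGCAGCACGAACTTT
ACACGGCATCCGTCACAACGTGATCTGAAGATCCCGGAGCGAGGGAACAGCTCGACACCC
GAGCTTGTATTAACGGGTTTCCTGACCACGCACCGTTGGGAGTTATGCCAATTGAGTGGC
TCGTCACAGCGCGAGTGGATTTCATGTAATTGTGCCAGCAGCCTGGGG
>TRBV19
ATGAGTTCAGCACGCCATAAGAACACTAAAACGAGGTGCCAAAGCCGACACCGGCGGGGC
AGCATAATGGGGCTTTTTCGCGTCCGTGCCTTGTCGCAACCTCTGGATCCCAAGGAATTA
TTGAAGGTGACAGCCACATTCTCCGGCGCGGGCCACAGTTTCCCTGTCAAAAGCATATAC
GTCTATCGAGACGAAAAGCGTTGTATAAAATGTGCCAGCAGCCTGGGG
>TRBV28
ATGGAGTACTATGAGGATGGCACATTTATAGCGTGGAATGCCCTAATATTACGAATAAGG
GTAAAGGAATATGGCACATCGTATCACTCGGGACAACAGGAGCGGCAAACGTGCCTGGCT
ACACTTCGCTTATGGGACTCGCTACAAAACTCATGTATTAGCAGGATACTCTTTTCACAG
CTTTGTTGGGGTCCTGACACTACCGGAACGTGTGCCAGCAGCCTGGGG
>TRBV6-5
ATGCTTCAAGTCTTAACTAACGTATGCATTCTTGGTACATTATGCCGTACGTCTGGTATG
GAGAATAGTTTCCAGAGCGTTCAGTGCGAACATATGGGAACGGCACGTGATGCAGTCTAT
GTAGGCCCAGCCCAATCGGCGAGGCCTGTAGTGCATAATACGCGAGTGGAGACGCCGAGG
ATTCATTCACCATCCCTCTTGGTGACGGTTTGTGCCAGCAGCCTGGGG
>TRAV12-1
ATGCGGAATCGCAAGCGTCTAGACGCTAGGTCTCCAATGAAGCCTCTCATGCGGGGAACA
CTCTACGTTCGAGCAATCCACTTACCAGAGGCTAGCGTTCCGCCGTTTCCTTATAGCGGT
CCCACCGCGCACAACAACCGAACCCCCCCGGATATGGCCTCGAAAAATACAATCGCTTAT
TATTATCAATACCAACTTGTGGTCGATAACTGTGCTGTGAGTGACACC
>TRAV19
ATGAACTATCAACATTCCGTTACAATGTATTCTTGGCTCAAGGCCGCAGAGGAAGTCCAA
CCATCCACCTCCTACTCGCCAGATGGCCGGCCAAAAGGCAGGTGCCCTTATAGAATCATG
AAGCGCTCGGGTCAGGTCTCTTCAATGGATGTATCACTATGTAGACATTTACGTTTGGAT
GCCGGGATGGGTCCCACATGCGTTTCTCCGTGTGCTGTGAGTGACACC
>TRAV29
ATGGCTTTAACAGTTTGGTGCTGGCGACGTATGCACCCCTCTCCTGCAGGCAGGCTCCTC
TCAGGCCATAAGGTCGCTTTGACCTTCAACCCCCTCCTACGTCTGCAGAAAACGCGCGGC
AAGATAAACAGTTTCAATAGCGGGTTCCTAGATTATCTAGCGTCATACATACGTGCACGA
TACGAGTGTTGTGTTGGACTTAGGTTCTATTGTGCTGTGAGTGACACC
>TRAV8-2
ATGACTTTACTTGTGATCGGGGTTAGACATCTACCATGTCCACATACCAAACTAACCACA
CTCCGTGATTTAACGCTGGGATCACAGGAGTGGAGAGAGGGGTCATCAGGTAAGGAGGGT
GCTTGTACTCAGCTCTTATTTAAGATCCCCCTCGTTTCCCTCGGTTCCTCACGATCTCGA
CGTGGTCCCCGAGCGCGTTGGACAGGTAATTGTGCTGTGAGTGACACC
>TRBJ1-1
ATGCTCGGTTCAGGGGAAGAGTTCGGGCCAGGGACCCGGCTGACCGTC
>TRBJ2-3
CCTGTAGTTCGCTGGATTACCTTTGGGCCAGGGACCCGGCTGACCGTC
>TRBJ2-7
AGCAGCCGGCTTTCTCGGAAATTCGGGCCAGGGACCCGGCTGACCGTC
>TRAJ33
GAGCCGGCAACTTTAGGCCTATGGGGAGGAAGCCAAGGAAATCTCATC
>TRAJ42
GAGGTTTCCTGCACCAGGTTCTTCGGAGGAAGCCAAGGAAATCTCATC
>TRAJ49
ATCAAACACCTGTCTGCTCTTTTTGGAGGAAGCCAAGGAAATCTCATC
>TRBD1
GGGACAGGGGGC
>TRBC1
CTGGCTCATGCAGTTCACGAGTACTATGTTATCGTTGACTTCACACCGGCTAGTCTATCT
TTAAGAGAGCCTCCACGTCGTGACTTTCGTGCGCGTGAAATGGCGGAGGTTGCCGTCGGC
>TRAC
CGTTCGTGTAAATTGGAAGATAGTCGTTATTACTTTAAGGTCTCAGGATGTGTGGGAGGT
CTGAGCGGTTCTTGGCGTGAGCTAGCGGCGGCCCGCATCAAATTTTACCTGGGTAAGCCC
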