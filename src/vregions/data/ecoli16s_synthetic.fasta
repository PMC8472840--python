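>ecoli16s_synthetic|numbering reference (synthetic stand-in, seed 1842)|1542 nt
GTACTCAAGAGTTTGATCATGGCTCAGGTCGAATGGGGGTCTCCTCATTCAACGGTTCCGGACGAGACCTCTATACACCA
GTCTAAGGACACATCGGACTGCGTTCATACCGCTAATGTTAAACAGCCTTCCTCGCACAGATCCTTGGAAAGGATTTCAC
TACGTACACAGTGAAGTTTTGACTCAGCGTAACGGATCAATGCAATAGAAATCTTGTGTTGTAAATTTAGCGGACGGAAC
AGGATCATCAGAGTCACCACCATGCAGCACTACTAGGGAGTGCGTTATGCTGCCAACCTGATTGAAAGACTCCCATACTA
CGGGAGGCAGCAGTTAGCGACCTACGGGCGGCTGCAGTAGGAGACGTGCTTATTGATATGTGAACTGATAAACCAGGGAA
GGGCGCCTGCCGGTTGCTACCCTGAATCCGAAGGGGCTATCCGATTAGACGGCTGCCTATCCTGCTGCAAATCGAGGCAA
TGATGTATGACCGACGGAGATGATTACTGGGAATGTGCCAGCAGCCGCGGTAATTGCTTGTGTATAACATCGGTCTACCC
TTAGCGTTGCCTGGTTTGCCACGCAAGATCAGTGTCCTTAGCTATATAGGTGTGCGTGGGGCCCATTAGTCATATGTTTA
CGGGCCGAACTCGTATCATGAAGACGCCCGCTTATTTTAGCAAACCGGCACCCTGGATTGTGTGCCGCAATTGGCAGAAG
TATCTAGCATCTCAAAACCTATTTCCGCCTATGAAATAGTCATTTGCAAATCAACATGGTAACCGGATTAGATACCCTGG
TAGTCCTGGTCTGGCCATAAGTGTTTTACGCGACCCACTTAAAAACTCGATACTTGCTTTGCATCCGCGTGAGATCGATT
CTTTAGCTTCGTACCACGTGGCCTTAAAACTCAAATGAATTGACGGGGTTCCCCCGTGCACGTCGTACGGCGCCGTGCGG
TGGCACGATGGCCACCAGCCACTGTAATTACAGTATGGATTGTGGAGTGTGCAATAAGTGCGAGCAGCAGAATCGTCGGC
AACCGTTTTACTGGATTTAATGATGAGGATCGTCTCCAGAGGCATGAACGAGTAACATCCAACGAGCGCAACCCGGTACC
ACGGAGTCATACACTAGGGCGGCAGTCGCGTCCGGTTTTGTTATACTCGATCGCCGGAAGGTGGGGATGACGTGTTGCCC
CTGCGCCGGAAGCATAAGCAGGAAGCTGGTCGTCGTTCCTCGCTGGAATAGGAATATACCGGTAGTAAGAGACTACCGAA
AATACCGTTTGGGTGATCAATACCACTGGCCAATGAACCCTGGTAATATCGTTGGGACATCTGGATATAAGCCATCGCAC
ATCCTGTGCGCGATGTCGCAACTGTCCCGTTACATGGAATACTTCCAGTACGCAACTGACTCGTACTACAAGGGTTTAAA
AGATTCTCCCGCTCCCAAATGTCGATCTGCCGAGTTGCGACAAGTGAGGCGAAGTCATAACAAGGTAACCGTAGGACAAT
CAGTCAGCTTAAGGGTCGCACC
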