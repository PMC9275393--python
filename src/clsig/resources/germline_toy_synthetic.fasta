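>IGHV1-2|V
CAGACCGTGGCTCGGCGCTCCACCGGC...ATAACCCTTTTGGTAGTCGGTGTTCTGACT
TCACGTCTGCCGAGGTGTGTGGCGCGATATGAA......CGGCGTATCACCGACTCTAAT
TCCTATCAAGCCAGCGTCGGGCCCACATTGCGGTCTGGAGTGGTCAGTCCCCTACTCAAG
...GAAAGCGTAGGATGTGTACCCTTGCGACATTGCCCGACACTAGTTAGTCGTACTGGC
CTACATATCGACGGATTACGGAGCTATGCCGGGACCCAGGTGTATCGGTACTCACCTTCT
CACATGGGATGT
>IGHV1-69|V
CAGTATAGTTACAAAGTTGTTGTGGCT...CTAGGGCAAGTGGACCGTCTGGAGAAGAGA
ATGACGCGGGGAGCTCTATCCGACACAGTCGAG...GCGGACGACACCGACGTTCAGGCA
AACCCACGGTTGATACAACGATTTTCCAAGATGTATAATTCCCAATGTCACCGGGCTACT
......GACCTGGTTTTTGCTCGACGACGCTACCATAGGCCAAACACGACCGTGGGTGGC
CGTGGTAGCTGCCTGTTAAGCCTCGGCCTCCGGAGCCCGATGCAGGGCGCCGCACCCTTC
ACCCCAACTTGC
>IGHV5-51|V
CAGCCCTGCCTCGGCCGTATTGTCTTG...ATTGTGATTGGTGTTCGGGTACAAACAACC
CGGTGCACTCGTGGGATAGGTCAGTACGAG.........GAAAGGCGTTCCAACGTCCTC
GGTGCTCGCCAGGCCAGAGATACCGCGGCCACCGTCCGAGTTAAGAGGCTCAGTCATGCT
...AGAGGAACGAGGGATGTTAGGCACTGTTTTGAGCGGCCAGCAGATCACAACAGCTTC
CGCCTACTAGTGAATACACAACTCGGACTCCGGTTAAGCGAGGAACTATACCAATTCCAT
GAACTTTCATGT
>IGHV7-4-1|V
CAGCGGCCCTATAAATCTGAAAGACAG...GACCAGACGGCTGGAACTCAAATGGCTGGT
GGTTTAGTGCATACGGCATGCTTGATCATGAAG......AGAGACGAACCGCAGTATCGT
TACTTCCATATATTCGCGCACGCCCTGTGCATTTTTTTAAGGAGCCTTAAGCACCGG...
...TTGTTTAGCTCTACCGTATCATCTATCTCTACGCTTCTACAGAACGTGCCAGCTCGA
CCGTCTACCGTAGTACCGATTAAATTATTAATGAACACTACATATTCTAGCGTAAGGCCG
GATGGTTCGTGT
>IGHV2-5|V
CAGCAACAGTTTGTGCATTTGCTCCTG...CGGAGATTAAAAAGGATCCAAACTAACGGA
TTGACTCACCTGTGTGGCGTCGAGCGCAGTTCCTAC...AACGGGACCGTATATACTCGG
ACTGAGTGTACACCTTTGCAGACTCTCCTGGCTCAGTTCCTTCACTTCTGTCTCAACGAT
...GACAGAGCGTCAACGGGTAGAGTACGCAAATTCAGCGATAGGTGTGTATACCGCCTA
GCGGTTTCAAACGCTACGCACTATATTGTTCGTATCCCACTTGTCGCATGTTCGGTCGCA
CACCGAACTTGT
>IGHV4-34|V
CAGCCGACGGCTTTCTCGCAACGTCTT...ATGCAAATGTTTGTATCATACTTCACGTCG
AATCTAGATCCCAGAAGTTATCATCAGTGT.........AGATGCTGTGATAGCAGCCAC
GAGAGCCGTACGGAAAACGGGAATAGTAGGTATAATCGCGATCTGGGATACCCTTAT...
...CATTTTCTGGTATCGGTTTCCGAAAAGCTCAGGTCTATGATCATGGCGGAGTTACGA
CAAAAGAAACCGTGTCTTTCTACGACCTCAACGAATCGATGTGGCACCTCATCATACTGC
ATGTTGCATTGC
>IGHV4-39|V
CAGTACGCCGCGGCAGTGGTAAGATAT...GAACATCTGTTGTCCTCACGTGTTCCTGGC
GCGATGATTAATAGACGGCTAAGCCGCGCA......ATCCCACCGCTGCCCGTACATCGG
CCGAGGGGCATGCACGTTTTAGGATGCTCCCTAGTGCATCGTGAATTCTCACTCGCT...
...ATATACGACCTTGTCGCCACACACAGGGTAAAGATAGATGGCCTGTCCTGTACTTTC
GCAGCGACCGCCGGTGAGACCCTTTTAGGTAGATTCTTCAGGTACCGAGATCGGGTGTTT
GTTTGTTTATGT
>IGHV6-1|V
CAGGGTGATAATACCCTTGCAAGGAGGACTGACAAAGAGCTACGTGGACTTGGTGTCTGT
GTTCTTCTCATGGATAGATGTTCAACTGTTACT......GGTACCCTCGCTGGTCGCTGT
GTGATAGGAGGTCCAGTATCTTATGTCGCGCAAGTTCCCCTTCAGCAGAGCTTCAGAACC
......TTAGACCGGGTACCGACTGGTAGGGACTTATTACCCGTGGCACTAAGACCGGCT
TTTAAAGGTTCATTCCGCACTCAATCCTCGGCGACTACTCTAGATAACGGCGAAAAAACC
CGTGGTTATTGT
>IGHV3-7|V
CAGTTGCGTCAGCGGAAACAGCTGTGT...GTAGTGGAAACGCCTTTTAAGTCGGGCCAC
GTGTCAAAGACGGCTTTTAACGCTAGAGCTGCC...ACCGGATCTTCCAACATGATGCGT
AGATCCGTGTACAGTAAATGCCACGCTTGCAAGAAAAAAAGCAATTATGCATTGTACTTC
...ATGCACTCAATGAATGGATACTTGTGTACTGTGTCAGGCTATTCACGGAAGCGTATA
ACGACTGGCCTGGAAGTAGAAGCCACCTCCCGGAGCTACGTAAATAGTAAACAAACCGGG
CTTTTGGTATGT
>IGHV3-21|V
CAGGCAACAGCAAAAAAGATCTCTCGT...GGGCGAAGGCCGACCGTGAGTCCGTTGGAT
CGTGAAGTTATTGCGTCGGAGCGGAGAATGTTA......GAACAGCGCGAGGAAGGCATT
GCGCGGTTAAGCAGACGTCTGGGCCGATGCCTAACTACTTTGAGATTACAAACCCAGGCA
......CGCGTTGCACGAGCGTTGCGAAGCCGATCAATCTTAGATGCACATTGTAAGCAC
CGCCTACTAAGAATCACCGAGCCCGACGATGGGGAAGCGGATGCTGCACAGATGGTTCCA
GAAAGTCGCTGC
>IGHV3-23|V
CAGCTTCCCTTCCTGTACGTAGACTCT...ACTTGTTCCCTGGTACTTCAAGTTATGCAG
CTTTCACCTCTCAAGACGAATACATCGTCA......TATAATACACAAGACCCACTCAGG
GGTCAGAATGTATGCAAACGGTATGGGTCCCGACCGGGGAGCATGGCAGGAACTCTGCCC
...CTGTTCACATTTCGGGTGCGCCAGGTGGGCAGAGGGGTCCCTTGTGCGCCAAAAGGA
ATAGTCCTTCTAAGCGGGAGCCGCTCATGTTTTTTCGACATATCATACTTTGCTAGACTG
CGGTCACCTTGT
>IGHV3-48|V
CAGTCAGTCAAGCGGCTACTATGTAGC...CAGAGGATGTGCTTAAAGGCCATCAGTCAC
AGTCTCTTTGATGGTCTCAAAACCCAAATGTCA......TCATCCGCGGACGCGCGAGGA
GTTGTCGCAAATGGTCCCGTAGAATCGCCATGTTCACATCTACTTGTGGGCTCCCCG...
CTGCGCTGCCAGGATACTTCCCCTCCAGAGCTCTCACTTCTTACGAACCCTTTTTGTGCC
GCCCCTAGGAAACCACAGAGTATTAACGCATGTGGCCGGCGCCAGAGAGATGACAAACGA
CAAAGGGGGTGC
>IGHD3-3|D
GTTGTCTTGTGGCTGTC
>IGHD6-19|D
TAAGGTCGGTGCTAT
>IGHJ4|J
AGCCACTGGGGTCAAGGAACCCTGGTCACCGTCTCCTCA
>IGHJ5|J
TATGTATTGTGGGGTCAAGGAACCCTGGTCACCGTCTCCTCA
>IGHJ6|J
GTAGCGCCAAAAACTTGGGGTCAAGGAACCCTGGTCACCGTCTCCTCA
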