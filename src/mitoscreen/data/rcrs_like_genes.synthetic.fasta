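>ND1 synthetic rCRS-like 3307-4262 heavy-strand
ATACCCATGGGGAATTGGGCCGCAGTGGAAGCTCAGCTCATTAATGTCTACAAACCGAATGAAGATGTTA
CATGCCAGGGCATTCGATGTAATCCTGGACGCGATATCTACACGGCAGCATTACTTATATGACCTGGAGT
CGGGTCTGAGCTTCACTTTGGGGCATCCACCCTCAATGCCCATCAAGGGAGCACATCATCAGGGCCGAAC
GCGACGAATGGATGGACAAAAGAACAGGAAGTAACTTACCACTATCGGATGCCCGCAAAGCCCTGATTGA
CCATTGGCCTGTTAGCCGGGCTGATCATAGTTAACAAGTGGGGATGGTACCATAATGACCCCGGATTCTG
AATTTGTGACGGACACGCCGGATTGCTCGATGATGTAGCCCAGGCCTTGACTAGCGTTAGCATACTTCAC
TATGTTAATGCCAATTGTCCAATCTGCATCCCCTCTAGTTGAGGCCCACGCCCCTTCCCAAACGATGAAT
TTTCAAACCAAGTCGTATTGATATTTCAGAAAGCGAAGTGTGCCTATTACGACATAAATATATGTTGAGG
CCTATGAGTTGGTCGGGCACGTCTATTAGTCTTATATGATATGGCTCCTAAGTGACGTGCAGATTTGCGG
TCCAGTGTTTTAGAGGTTCAAACATCTGAGATATTGCCTAGTACGCTGTCCACTTCCCCGAATTGGGTCC
GGAGTCAAATTACTCGATATACTTATCCTTTACAAGATATAGTGGAGCTCAAATGATGCCGGTATCCGCT
TTCCTCACGTCGTATGGTTGGCAACTACTGTCCATATTCAGATGAGGGTATCCCCCGACGTGAAATTCAG
TATCAGCTGACTAACAGCCGTGTCTTCCCAAATCACTATGACTCAATTGCATTTTACCTATGGGTCTTTG
AAATTTATTGGGTGATTTTTCCCGTACAACGGCTTCAATTTGACAC
>ND2 synthetic rCRS-like 4470-5511 heavy-strand
ATTGACTCGCCTGCATTATATTTTCCGACTCAAGGCTGTCATTATACCCCAGTCCTCCGTTCGTTATCTT
GGCGCGTGGGCCACTTGAACATGTGTCCAAAATCTAATCTCACGATATCGTATACCCCCGCGGCCGGGTG
TGCAGGATCCTTCGACGTCGATGGCTCAGAGTTTCAATCAACCTCGGATACCGTTTCCTTCTGCCTTTCT
GGGAGTAGTCCCGTCAGTTTGGGCCCAGGGCCACTACGACAGCTAGTCCCAGGTATTACTAAAACGCTTG
CTTTGCCGGCTGTGCAATTTCTGCCGTTCTGCTCTCGGATCGCAGCGGTCTGCCAGATACAAGAACCGAG
TGTCCTGGCCCCACGATCTCTCCGGAAATGTGCACCTCATCTGGGGCTGCGCTACGAAGCGGGTTCGAAG
ACGAAGGACATTGTTGCCATCGAACAGCGACTCACGCCTCCGAATCTTGACTGCCTCCCGGTAACCAGTG
AAAGTCTGTCCCACTTAACAGAGATAAGCTGAGATCGCTCGCAATTTGGTTGGGTACAGGGTCAAACTAT
GATGGTGCGACGCAAAGCCACGTGGCGGACGGCGGCAGCATCACTACACGACTACCTGCTGGAACGAAGT
CACCATTTCTCGATGCAAGGCACACCCTTCCTCCCCTGCCGATTTGATGGTAAAGAAATTCCACGAGATG
GAGACAGTCAACTATGCGCACAGGGTAGTCCATACATGGGCCTTGGGATATCTCCTTACCTCGCACGTAC
ACCGCAATGGACTACAATGCTGATGGACTCATACCTTTACTTTGGTTGAACAAAACGGCAAATCTGGGAG
CACCTTTCGTACGATCAGGACCTTGCACTAATTGAAACGCGTCGTATGTACCCTTATCAATACCATATCC
AATTAGAGCTTGGTCTAACATATCAGCGGTTATCAGATCATGTTAAAGAGAACGACTTTGTATTGGCCCA
TCAGCTCCGCATGCTTACCTTTCGATCAACCCAGCAATCCGGTCAACCCAACGAAACGATGA
>ND3 synthetic rCRS-like 10059-10404 heavy-strand
ATAAATTTCCGCAACGCGACACTGCCCAACTGTACCACCTTAGGTTACTACAAGTGAGGTGCAAAGATTG
AAGGACTTTTTATCTTCATAGGCCTGGTCAGCCCCGGGCGACCGATATCGACGCCAGTGCACTCCTTTCA
TAACGGAATTGCAATTAAGCGACAAGTGGCTCATGGAAAAGTATGACGTAAGATTGGCGCTTTCACGCGT
TGTGGGTTCAACATCGTGACACTGAATACGGGAGGCTACCTGGATACGAAACAAGGCAGCATCTCCCTAT
ACGCAAGTAAACCATTTTTTGAATTGCACCGACCCTTATCTGGGGGCGCGTTCTGATTGAGTTACA
>ND4L synthetic rCRS-like 10470-10766 heavy-strand
ATGTTTAGCCGCCGCTGGGTGAACGTTTATATGCTGGCGTACCGCAATAGCAGCATGTTTCGGCTCGGGG
ATTTGACCCTGTGGTTTTGATGGTGCATATTCCGAAACAAACAAATTAGCAAGCATTTTTCTGCCGTCAT
GCCTGGGACGAATAGCAGCGGACAGTATCCAGATCGTTTAGGGGAACCTCGACCTTTCTATCTATGAGGA
GCTGGCGTGAAGATGTCCGGGCTCGCTGGATTCTGGCTCGTTGAAACGCAAGTGCTGGAAATATTTGGTT
GGACGCCATGTTCGTAA
>ND4 synthetic rCRS-like 10760-12137 heavy-strand
TTCGTAACCATAAAACGCAATTCGAAAGCTAAAGGGACGGCCATTCGTGATGACCACACGTACGCGCCCG
GCCCAATAGATGCGATGCCGTATTTGAATAAGTCAATCATCTTGTGCTATCATCATTTCCGCGTTATAAT
GTCGTGTCAAATCTACAATGCCCGCCTACTAAGCTATTACACGGGGGCATATCTCCCGCCGGGTCACCTG
ATAGTCCATCATTCCTTTTTTTCAATATGGCGATGGGCCCGAACTGTCTCCTCATTATCGGGCAAACACA
CTGGAGGTCACACATCGTTTAACTGACTCTTAACGGTTGCAATATGGATCGCTTCGTACTGATGCGTATC
TGACAAGCAGCCCTACGCGCCTCGAGGGAGCACTGCTGTCTTCTACTCCCTCGAGACTTTTGCGTCACCA
GCTCAACCCCAGGGACAACGATTCACTGTACACGTGCCCGCCTCGGCCCTTGTCAACTCTCACTGTAGCA
GTTGTTCGCCTTATGCCTTAATTCAGTGCACTACTTCACGGGTCCAGCTAGCCTACGGTGGATCACTGGT
ACTGTCGTTACCGGAACAGAGCGGGTATTGTAGTACCCCTTGCAACCGAGAACGATATCATCGAGGAGAC
GGGACGGTTGGCGTAATAACATCAAATAGTTACCTCGGGCCGATACTACTTCTGCACCTAACCGTTAACG
CGGTTTCCTCCCCAGCGTGGCCATGCGAAGCGGAAGGCGCCGCTCTTCCGAGTAGCTACCTGCCCGATGA
AGCTATATCGTATCTACTGCTCTGACCATTTATTATGAAGACTGCCATGTCTGCCGCGATTGGGAATTTA
GCTCTCCGCACAATGTGTCATGGTGGAAACTGGAAAACCCGCCGGGACCTTTTTCCTGGGCAAGTTATTC
ATCTAAGTTGAGTTATAGAGCGAAGTGGCGGTGCTTCCGTCCATGTTCTATTCCGGTCCCTAATGTGCGA
ACCCGACTACGCTCCACCGTCGGTCTGGAAGCAAAATAACGCATTGTCAGCGCGATTGATGGTTCGGTGT
ACTAGCGTATGACCTCACGCGTGACGCGGGTCTATGATTAGCTGAGTTAGTCTGCTCTCGTCCTGAGCCC
CAGTAGCCGGAGCCACAGAACTATTACGGATCGCGTCGTTCGACACAGGGATTCGCTTGCGTCATAAAAA
AAACGCTCTCAATCTCCCGGCGCTGCAATCTGAAAATATCTGGCTAAATGTCATGGGTCGTACTACCTTG
ACAGTGACAACTGACAAACTCCTCTTGAAGCCTTCTATGAACCCGACTGACGTGGGCGAGTCAATGGGAG
GGGTCAAGCGACCGTTGCAGGCCGGCCACACCAACGATTGTGGAGAGG
>ND5 synthetic rCRS-like 12337-14148 heavy-strand
ATATCTTCATACTACAATTCCTGCTCGGTTACTGACGAGGTCCCCGTTGGAGCGAGCGAGCATACCTGCC
CAGATTTACACATCCGAGGAAACCACAACCTTTCACAACACGAACGCACTCGGATGGATCAGGGCGTGGC
AGTAGCGGGTCCAATGATAGCTCGAGGGAATGCTCCTCCACAACCTACAAAACGAGCTGATTCGTGGATG
ATGATCCGTACACGGAGCTTAGTGCATAATGCGGCCTTTTTTCAGTCATTAGGTAAACCGTCTTCTAGCA
CCCAAGGTGTGATCGCCGGCTGGCCCGGATCGTCGGTAACTACTACCCGCTGGTATCTCCCACTATGACC
ACGCTTCTTTACTCGCCTTATCTCCAAGCCTCCATTTCGTGACCAGCGATTCCGGAATCTAGTCGATGCC
AAGGATACTTGCCCACAATGTATCTCATACGTAAGTACCGTACGTTTAATTGCGACAAGCTCGTCATATA
CTTCCGTATGTTCCACCTCTAAGCAAGGCCGCTCTCGTGGCGGTCTTATTGGCCCCTTGTTACATCCTAG
CCAGTATACAGACCCAACGTGGTCGGATTATACGTTGCAACCCCTTCAGCAGAGTTCAACAGTATCGAAG
AGCATCCAAATCGCCGCCAGCTATACGGAACGCGTCGATCATTCCTGATGGCGGTGTCTGCACACCGCGT
ACTCGTTATGTGAATCTAGTCGACCAAATGAGATTTTGGCGCATTTACGGACGATCTGCCTAGGTGCGAT
CTTCGCTAGTTACCGGTGCAGTGTCGCCAAAAATCCCTGTGGGACAACAGCAAAGCGCGTTCCTTTAACG
TACGCTACCGATTCAGACCACACTTGTCTGGACCGAGTTGGAGCTCTTTGTGGCGCCTCGTGAGCTCGAC
CTACTGAGGTTTGAGCCTTATTATGACGCTTGACGGGCCGTACAAGTCTGGGCGGCTGCTATCAGATCCT
GTCACACTGGTTCCCTCCATGTACCCCGGGGAGTCACGAGTTTCACGGAAGTCATCGGAACTATGGGGAT
CCACTCCTTTGGTTTGACGTCGCCAACCGTCGTGCCGCGACCATCTGCCGACCTGTCTTGTCGTACCCGG
TGTATGCCTGAAAACCTATTCTGGCTCCCGTCGAATTTTTGTACTTTGTAGTCTGATGAGGGGAGCACCA
CTCTGGACCTTTCCAGCAACATACGCTTCTGTCCCTTGACCGGCAATCTGAAGCTGGCAGCCTACAAGGT
TTGTCTAGTTGCTGACATACTCACACCGATACTCCACGCGAAGCATATCCCTGCGACGACTCCTCACTAG
CAAGCTTAAAGCCCCATTCGGGTTTCGCAACATCGGAGTTATTTGGGCACGGTTTTGACCTCAAAAAGCA
TGTAACAGACGCTCAAATGACCATAGTAGAGTCGCTCAGTAAGACCATGAGCCGTAAGTGCTCTATAGTG
CACGCGGGATTCACTGCCCAGGACACTATACTTAAGACTAAGTCTATCCCTCTGCCAGCCTGTTGCATAC
AGCAAGGAACGCTAATGACTCCACTGGTTTCATCACCCCCGAAACCAGCGCACCGCGTTTCATGGTTCAC
ACGAATCATCGGACCCACAGGCGGGACGTCTTTAACAGCGTCGGATGAGCACCTCGTTCTATGAGTACCT
AAGCCTCCCCCCGGTCTTGCGCCGATCGGACAGCCAGCAATCGCCAAGGTATCTCTTCCTCTAATGTTAA
TATATTGCGCTGACGCCTCGGTGCACACCTCGCGCAATTCCAAGAGCTGAATCTGTACTTAA
>ND6 synthetic rCRS-like 14149-14673 heavy-strand
TCTAAATATTCAAGAATCCTCGTGGTATACTAGGGAGCTCTGAGCCGAGAGAGTACGCGGGTGTTCAGGT
ACCGCCACATCGCAATCCGGCGAGGAGTTGAGGCAAGCTTGCACTGCATGGTTGAACATTATCTGATTTC
CTGAGCACTGACACAACGAGAAGGAAGTGCTGCAGTCATGCGTCCCCGAGCATAACCCCGGGGTAGTCGA
TAACACCGGGCGGCGGCTGCTCCGAGAGCGGTCCGAGAGCAAGTGACCCGGGACCATGTAAGTAAGGAAG
GAAGAGACATGGATACCACAGACGCTGTGGTCCTGCATAATTATCTTCAGAACGTATATGAAAGCACACG
AGAAGCTAGACTCTAAGGAAACGTGCATTGCACGTGGCCCCACCGACACTCGCTTCTCCGCGGCACATAT
AACGTGTTGACACGTCGAATGTACTTTATCGGGATCGGCGTAATGCACCTTAGTCGCATGGCTAACTGTA
GGCAATAAGTCAACTGCCGCCGGTTTCGTCGGCAT
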