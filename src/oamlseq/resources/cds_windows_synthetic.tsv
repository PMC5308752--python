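gene	chrom	start	aa_start	seq
BCL10	chr1	85733000	100	TATCTAACTAAAACCTTCTTTTTTTCCGCCAAGGGGGTAACCACGTATCCGATTAACAACTCAAACCCGGGCGCTCTGGCTCTCAGCACCAGTGTCACTTGCAAAGAACTTTGTATTACAGGGGAGTTCCTCACA
BIRC3	chr11	102188000	300	GCGGGTACCGAAGCCAAGCACTCGGATACAGGCCATCTGTGCCCGCACATTGGCTTGATACTCTGTGACGGGAACTTTGAAACAAAACCCAGCGTCCTGGGGCGAAGGAATACAGCCCTTAGGACAGATATCAGC
CARD11	chr7	2946000	200	AACTTGCCGTATACTGACAGCGGGCATCTCAAGCGGCACGGGTCCAAGAGTCACAGCCATTGCAGCTATTCTCTCAAGGCACGATACCCGCTTCCCGCCTCGCTCCTGAAGTCATTGCTGTGGTCGGCGTGTAGG
CD79A	chr19	42381000	50	CTAGTGTATGACTCGCTACAGCACACTTATAGTCGGCGTTATACTTTTGACACGTCTTCTCTTCGATCGTCGGGGCAAGGCATACCGACGGTAGTATCCAGGGCCTTCTTTCACAGCTGCTCTGTGCCATCATCA
CD79B	chr17	62006000	150	CTAGTGACAACCCGCATCAATTTACAGTCCAAGATGGAATCTACCTCATTGTTTGTACCACATTTTCTCACAGCCCAATGCACAGTACGTTTTATAACGCGCATAGTCTGTTGTCTCGAAATTTCGTCCCCTTTG
CYLD	chr16	50775000	400	TGCATCGAATGTGTACGGAGTTTTGCCATCCATAATTCGCCGGAGAGCCTTTTCTATTTTGATCTGCCCAGAAGAAATGCTAGGTTGAGCTCTGAGACAGTCCCAAGGAAAGGGGGTAATGGAACCTACTCAAGC
FAS	chr10	90750000	120	TTCATCAAGCGTCGCGTTCCAATCTCGGGTCGATTGTGGTTCCACGAGGGATTCCATCGTCCAGGTGCATGCAGCTCTGAGACCTACCAACACCGGCGCTGCGCACACGACACTGTACGACACATCCATGTCTCT
IKBKG	chrX	153770000	180	GCCCGCAATCCGTGTTCTCTAATGTATCTTAGGCGACATAAAACACTGCGCCATCGTTCTGGTTCGCTGAGTCGCGGACTGAGGCAGGCCCCTGGCGCGCCGATCAGGGACTTGGCACTCTCCGGGCTGGGGAAC
KMT2D	chr12	49420500	5420	TCCTCAGTGCTCGGGTCCACGAACCCTTCACTGACATTCAGATGTTTATTAGCCCCCCCGTACTACCAGCATGGTGGTGCCCCCGCATTTTTTCAGGCAATAGAATCGGTTCACACAGAGGTAGCGATCCCCGAA
KMT2D	chr12	49425000	2500	CCCTTCCCACTCCACACCTACGACGCCGCCGATACTTCGATTCAACCTAGATGGAACCGCAAGGGGAAGATCGGGAGCCCAGACCCGCGTTTCGAATTCACATGCTACCATCAAGTACTTTTCGCCATGCCGGAAACCGGCTTCTCCAACGGTGCCCCCTGGGCAATGAGGCTGCTTGGT
MALT1	chr18	56338000	300	TTTGGTTTTAGATGTGAGGCTGCTACAAGCGAGTTTTCTATTGTAAGGTTCGAATACGAAGTATATCGCTGCTCTCCAAGAGTCGATGCAGAGGCTGCGTGCCTAAAGCCTACATTGCCTTACTCTGGTCGGTGT
MAP3K7	chr6	91223000	200	AAGGCGGCTACACCAATGGCTTCCATACCGTTTTTTGACGTATATCGAGCCCTTAATAACCTATCCACCTCTCAGCGTTTGCCCAGCCTTGGTTACGGCATTGTATCAAACTGGGTTCCGGCCCCTCGGAGTACA
MAP3K14	chr17	43340000	400	GGAAACATCTATATATCTGCGGCTGATGTGAGCGAAAGAGGTTTCCAAGGCGTTAATTTTTTCGCGCTCCCTGCGGTGCCTCAGCGCCGGTATCCTATGCAGAAATTACCAGCCCACACTGAGGCGAAGTGGATC
MYD88	chr3	38182565	240	GAGGCAGCCCCTGAGAGTCCACAGCCTTCTTTGCACGTCGTAGGCAGTCTCTTCAGGTGTAAAGAGGTACGGATTCTGATACTACACTCTTGGGTGAGTCCGTTTGTTGCCTCGTGCCGGGACCTTTACGCGGCCCTGTCGCTGGAACTAGTGGTGTCCGTTCCTGCTACGGTCGGTGAC
NFKBIA	chr14	35871000	100	TGCCGCTCTGCCAGAACGTCACTGCTTACGGAGGATAGATCCTATCAAATTGTAACACCCCGCCAGGTCGACCCGCGCGATTGCATAGCGCTGGGTTTGGGTTTGCTCCCATTTCTATTCGACACGGAGTCCCTC
NOTCH1	chr9	139399000	1580	ACCACAATAAGTGCGTTACCCAGTCGACACGTATTGATACAAAACAGGGGGCCAGCGACGAAGAATTCCGGTCAACGTCCACCCCATGCCTTGCGTGTCGCATTAGGTAGGCGACGCAAACAGGCGGCGTTCCAG
NOTCH1	chr9	139390800	2480	TTCTCTGTCCCATTGTGCGCTATTAGCTCTTTCTGCATAGCTCTAGCGCTACGGGAATGCCCCGACCACTCCTGTCGTCGCCAAGGTGCACTTCCAATTTCTCAGAGGAGGTTACGGAGGAAGATGGCAGAGTTCCCGGGAGAGATCCGTTTCCTAAACGATCGCTATACAGTCTGTGTCACAACATCGATTTCGGGCCGAGTCTGTCTTCGATATTCAATTGTACAT
NOTCH2	chr1	120458000	2150	TCTGAACCATCGGACGACCTATCCGGGGGTACACATTCCTATAACTCCTGCGAAAGTAGCAGCCGACGTAGTGACAGATTGCATACGCTTGAGTCCCCCGCGAGACACTGGTTCTATTTTCGTTGGGTTCTGCAC
NOTCH2	chr1	120459000	2410	TGGCCAAGGACATCACTAATGCTAATTTACACACACTCGAGCTCGGGATCTGATCACAGCCGCATCATAGATGACAGCTTCATCCCCGTGGGTGCTCGGGGTAAAGACCCGTGTATAGGCATGTCTGATAACAAC
RIPK1	chr6	3064000	250	TGTCCTTCGCTAATTGGTTACAAACGGCGTCTTCGGCCCTTTTTCGGCGCCGACATTTACGCCTATGCATATGTGGCACTTCATCTGGCCAACAACCAGGTAGCAACTTTGCTAGCATGCTACATTCGCCGGATC
RIPK2	chr8	90770000	200	AAGCGTCGCACTCGGAGTTGCAGTGCTACATTCTCAGTGCCTTCAAGGGTTTACATGTCCACAGAACGAAAGAGACACGGTGAAAACCCGGAAAATTCCCACGTGGACAACTTCAAGCGGTTTCTGAACGTCTAC
TNFAIP3	chr6	138192000	280	CAGTGTAGTATGTGCGCTCTTGCAAATTTACAGATTCTACTCAGTCAAAGGCGGGGCGTTCATGACTTAAAATTCCAGTCTGGCCCAGGAGCGATCTTCAGTGTAAAGGGCCATGGAGTTGCGCTTTTCAACCGTAGGCGTGGCCCCGCTCAGTGGACGTGTACCTCTGCAGTGCGGGCA
TNFAIP3	chr6	138196000	587	TTACCCGACGTCGCGAAGGGGTCCCGGTTTCTAGACAGTCGCACGGATTTAGACCCCGGCGCC
TNIP1	chr5	150410000	300	GACGAGATAGGCGACACGCGCACCCCAGTAGAAAGAGGATGCTTTACAGGCGGCCCCGTGTCTGCTCTGCAATGCTGGTATACAACATTCGCGCTATATGCTTGTAAACCGAAGGCCGCTATCACGTCCGGGCTA
TNIP2	chr4	2743000	200	GTAGATAGTTTCGCAAAGCACGAATCTGGTTACGCCTCGCGCCATGCCTTTGCTAAGGGGGCAGGCCCCTGGGAGCCCGTTATCACCGACTATATTTTGACGTATCATAACACAACCAACTCTCATGATGCTCCG
TP53	chr17	7573000	150	GCTGGTGGATCGCGTGCTTATAACCGCCTCACCATCACCCCGGGCCCCCCGCGACCGGTAACGAACAGAAGACTACCGGTCGTTAGAACGAATCACGCAAGGAAGGCTCCCGATGCTCTTGCGACCGAATCATTT
TRAF3	chr14	103240000	300	TACCGTGGTCCTTCTAACCGGTTCCCAATAGAGAGGGCTTGCGCAATGGTCCGTAGGGGACGTGTACTTGGCAGACGAGAAGGGCTGGTCGCACGACATGCACACCAAAGCCCGAGAGTAGGGTGGTCCCAAGCT
TRAF6	chr11	36510000	250	CATATTCAGAGGAGCGCGGGAGCCGTTCTCAATCAACGGCCTTGGAATTTCCCGGGATCATATGTCTCAAAAGAAAAGATAGCTCATATACTGTCGGGTCGAGGCTGTGGTGGTTCCCAGCCATTGGATTTCCGA
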