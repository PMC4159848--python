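>synthetic_rt_cds synthetic reverse-transcriptase-like coding sequence; designed in silico around canonical RT motifs for simulator fixtures; not a natural sequence
ATGCCTACGCTGCGCTTTCAAATCTACAACAGCGATACGGCCCTTACCTGGTGGCAGCGTCGTACCCGCT
TCTGTGGTAGCCAGTTCGGAAAGATGTCATTTGCATTTACGGTCCGCCGCCGCCCAATTTCTATAGCTTG
CTGGAACGCACAGAAGACGTGGATAATGCAGTCAAGCCATGCAGGTGGTTTTTGGGGCGATGAATACAGA
GATTGTGGTAAGATGATTCACGGTTTCTTACAAACGGTTCTTTATTACTTCTACGCAGAGTCTATTCCGC
AGGGCTCAGTTACCGAGTGGTGTTTCTGTAAGACGATCGAGAGCAAAAAGCAAAAATTTATGTTCTCAGA
CCAAGATGATTGTGCAATCGTAATGGACGTTCAGGACAATCTTTCATTTCAGTTACAGATCCATCTGTTC
ATGGGCTGGGCTGCTCAAAATGGTCATGTCAAAACAGACATAGGTAATATGGTTTGGGGCGATTTCATCA
AACACTGTGATATATGCAGAGATTTCAGCTTTGAGGAAAGCGTCCACTTTGAGTCATTAATAATGAACTG
GAACAGCGCCTGCGAGCAGGCAGATAAAGGAGATACATGCGGCTTACTGCAGGGTTTCATCAGCGTATGG
TACAGACGTACCGTAAGAATCTATCATTCTATGTTTCAAGGTTTTATGTTTGACTGCCTTTGGTTTAAGA
GAAAGAACTACTGGCAGGCATACGCTGACGATGAGCCGTACTGGATGAACCTGATTCCGAAGGCTAAGAT
ATGCTACCAGATGAACGATCAAGCATCTTACCATCTGTTACGCGAAGCAAAATCTGGCCTTGGCGTCTCA
GGATGGCAGCGCTACCCTCCTGGTTGGGTCGCTTGGAAGAGCTTCGCTATGTGGCCAAACATGACCGCAG
ACGCTTGCCAGTGGCATTACTGGTACAATTTCAATGACTTTGACTATGGCATGATGGCAGGACATTTTTT
TTGGGTTGCTTAA
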