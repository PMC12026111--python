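>anneal_sensor_F label5=TEX chirality=L
ACTGGGTTTTACAAACCTGTGA
>anneal_sensor_Q label3=BHQ2 chirality=L
TCACAGGTTTGTAAAACCCAGTTCCAT
>melt_sensor_F label5=HEX chirality=L
ACAAGAAAGGGATCTTCACTCGCGACCGCAAACCGAAGTCGGCGGCTTTTCTGCTGCAAAAACGCTGGACTGGCATG
>melt_sensor_Q label3=BHQ2 chirality=L
CATGCCAGTCCAGCGTTTTTGCAGCAGAAAAGCCGCCGACTTCGGTTTGCGGTCGCGAGTGAAGATCCCTTTCTTGT
>smitis_forward_primer
GCCATTGAAGCGGTTACTTTG
>smitis_reverse_primer
CATCCGACATTAACGCAAGTTC
>smitis_probe label5=FAM label3=IABkFQ
ATGATTGAGCGTGGAACGGTGGGT
>smitis_target
GCCATTGAAGCCGTTACTTTGAACGCAAAAGTGGCTATGATTGAGCGTGGAACGGTGGGTGGAACTTGCGTTAATGTCGGATG
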