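id,pair,sequence,AA,AT,TA,CA,GT,CT,GA,CG,GC,GG
1a,1,CCGCGG,0,0,0,0,0,0,0,2,1,2
1b,1,CGGCCG,0,0,0,0,0,0,0,2,1,2
2a,2,GGACGTCC,0,0,0,0,2,0,2,1,0,2
2b,2,GACCGGTC,0,0,0,0,2,0,2,1,0,2
3a,3,CGTCGACG,0,0,0,0,2,0,2,3,0,0
3b,3,CGACGTCG,0,0,0,0,2,0,2,3,0,0
4a,4,CAAGCTTG,2,0,0,2,0,2,0,0,1,0
4b,4,CTTGCAAG,2,0,0,2,0,2,0,0,1,0
5a,5,CGGTACCG,0,0,1,0,2,0,0,2,0,2
5b,5,CCGTACGG,0,0,1,0,2,0,0,2,0,2
6a,6,GATCCGGATC,0,2,0,0,0,0,4,1,0,2
6b,6,GGATCGATCC,0,2,0,0,0,0,4,1,0,2
7a,7,ATGAGCTCAT,0,2,0,2,0,2,2,0,1,0
7b,7,ATCAGCTGAT,0,2,0,2,0,2,2,0,1,0
8a,8,TGCCGCGGCA,0,0,0,2,0,0,0,2,3,2
8b,8,TGGCGCGCCA,0,0,0,2,0,0,0,2,3,2
9a,9,CATAGGCCTATG,0,2,2,2,0,2,0,0,1,2
9b,9,CTATGGCCATAG,0,2,2,2,0,2,0,0,1,2
10,,AGTCATGACT,0,1,0,2,2,2,2,0,0,0
11,,GCGAATTCGC,2,1,0,0,0,0,2,2,2,0
12,,ATCGCTAGCGAT,0,2,1,0,0,2,2,2,2,0
13,,GACGACGTCGTC,0,0,0,0,4,0,4,3,0,0
14,,GCAAGCCGGCTTGC,2,0,0,2,0,2,0,1,4,2
15,,CGATCGGCCGATCG,0,2,0,0,0,0,4,4,1,2
16,,CATATGGCCATATG,0,4,2,4,0,0,0,0,1,2
17,,CAAGATCGATCTTG,2,2,0,2,0,2,4,1,0,0
18,,CGCGTACGCGTACGCG,0,0,2,0,4,0,0,6,3,0
19,,CGCAAGCCGGCTTGCG,2,0,0,2,0,2,0,3,4,2
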