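id,sequence,meas_dG37,meas_Tm,pred_dG37,pred_Tm,calc_dG37
1a,CCGCGG,-5.7,36.0,-4.2,35.3,-4.7
1b,CGGCCG,-5.7,36.9,-4.2,35.3,
2a,GGACGTCC,-5.3,35.4,-5.1,35.4,-5.5
2b,GACCGGTC,-5.4,35.6,-5.1,35.4,
3a,CGTCGACG,-6.1,39.0,-5.5,39.5,-5.9
3b,CGACGTCG,-6.2,39.3,-5.5,39.5,
4a,CAAGCTTG,-3.6,28.9,-3.8,28.3,-4.1
4b,CTTGCAAG,-3.9,29.6,-3.8,28.3,
5a,CGGTACCG,-4.6,32.3,-5.2,33.3,-5.3
5b,CCGTACGG,-5.4,34.7,-5.2,33.3,
6a,GATCCGGATC,-5.7,37.3,-6.0,40.4,-6.2
6b,GGATCGATCC,-6.0,38.2,-6.0,40.4,
7a,ATGAGCTCAT,-5.0,34.3,-5.2,34.9,-4.7
7b,ATCAGCTGAT,-4.9,34.0,-5.2,34.9,
8a,TGCCGCGGCA,-9.4,53.9,-7.9,49.8,-8.5
8b,TGGCGCGCCA,-9.3,54.8,-7.9,49.8,
9a,CATAGGCCTATG,-6.5,39.8,-6.4,40.3,-6.4
9b,CTATGGCCATAG,-6.8,40.5,-6.4,40.3,
10,AGTCATGACT,-4.5,32.3,-4.5,31.0,-4.7
11,GCGAATTCGC,-7.0,43.1,-7.0,43.1,-7.2
12,ATCGCTAGCGAT,-6.7,43.1,-7.4,41.9,-7.4
13,GACGACGTCGTC,-9.1,48.2,-9.1,50.1,-9.3
14,GCAAGCCGGCTTGC,-12.2,58.5,-11.6,57.2,-11.7
15,CGATCGGCCGATCG,-11.5,56.9,-11.3,48.2,-11.5
16,CATATGGCCATATG,-7.2,40.7,-7.6,44.3,-7.4
17,CAAGATCGATCTTG,-8.2,44.6,-8.3,44.1,-8.1
18,CGCGTACGCGTACGCG,-13.6,57.9,-14.4,59.4,-14.4
19,CGCAAGCCGGCTTGCG,-14.8,64.2,-14.2,61.6,-14.3
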