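id,sequence,dH,dH_err,TdS37,TdS37_err,dG37,dG37_err,Tm,pred_dG37_dilute,pred_Tm_dilute,ddG37,dTm
1a,CCGCGG,-49.8,3.4,-44.1,3.1,-5.7,0.5,36.0,-6.6,43.0,0.9,-7.0
1b,CGGCCG,-43.0,3.1,-37.3,2.7,-5.7,0.5,36.9,-6.6,43.0,0.9,-6.1
2a,GGACGTCC,-63.0,2.8,-57.7,2.6,-5.3,0.4,35.4,-7.5,43.1,2.2,-7.7
2b,GACCGGTC,-64.1,6.0,-58.7,5.5,-5.4,0.8,35.6,-7.5,43.1,2.1,-7.5
3a,CGTCGACG,-63.9,2.2,-57.8,2.0,-6.1,0.3,39.0,-7.9,47.6,1.8,-8.6
3b,CGACGTCG,-63.2,3.7,-57.0,3.4,-6.2,0.5,39.3,-7.9,47.6,1.7,-8.3
4a,CAAGCTTG,-79.7,2.4,-76.1,2.3,-3.6,0.3,28.9,-6.2,35.2,2.6,-6.3
4b,CTTGCAAG,-72.5,3.4,-68.6,3.2,-3.9,0.4,29.6,-6.2,35.2,2.3,-5.6
5a,CGGTACCG,-69.5,2.7,-64.9,2.6,-4.6,0.3,32.3,-7.6,40.8,3.0,-8.5
5b,CCGTACGG,-60.5,5.4,-55.1,5.0,-5.4,0.7,34.7,-7.6,40.8,2.2,-6.1
6a,GATCCGGATC,-82.5,5.1,-76.8,4.8,-5.7,0.7,37.3,-8.4,48.7,2.7,-11.4
6b,GGATCGATCC,-77.9,2.2,-71.9,2.0,-6.0,0.3,38.2,-8.4,48.7,2.4,-10.5
7a,ATGAGCTCAT,-71.8,0.9,-66.8,0.8,-5.0,0.1,34.3,-7.6,42.5,2.6,-8.1
7b,ATCAGCTGAT,-77.1,2.0,-72.2,1.9,-4.9,0.3,34.0,-7.6,42.5,2.7,-8.5
8a,TGCCGCGGCA,-71.0,4.7,-61.6,4.1,-9.4,0.8,53.9,-10.3,59.1,0.9,-5.2
8b,TGGCGCGCCA,-61.8,2.7,-54.5,2.6,-9.3,0.1,54.8,-10.3,59.1,1.0,-4.3
9a,CATAGGCCTATG,-86.0,4.3,-79.5,4.0,-6.5,0.6,39.8,-8.8,48.5,2.3,-8.7
9b,CTATGGCCATAG,-91.9,3.6,-85.1,3.4,-6.8,0.5,40.5,-8.8,48.5,2.0,-8.0
10,AGTCATGACT,-69.8,4.3,-65.3,4.0,-4.5,0.5,32.3,-6.9,38.2,2.4,-5.9
11,GCGAATTCGC,-66.9,1.9,-59.9,1.7,-7.0,0.3,43.1,-9.4,51.6,2.4,-8.5
12,ATCGCTAGCGAT,-59.8,9.0,-53.1,8.0,-6.7,1.3,43.1,-9.8,50.3,3.1,-7.2
13,GACGACGTCGTC,-95.0,4.4,-85.9,4.0,-9.1,0.6,48.2,-11.5,59.4,2.4,-11.2
14,GCAAGCCGGCTTGC,-96.2,8.2,-84.0,7.9,-12.2,0.4,58.5,-14.1,67.3,1.9,-8.8
15,CGATCGGCCGATCG,-90.9,8.5,-79.4,8.3,-11.5,0.3,56.9,-13.8,57.3,2.3,-0.4
16,CATATGGCCATATG,-129.4,5.8,-122.2,5.5,-7.2,0.7,40.7,-10.0,53.0,2.8,-12.3
17,CAAGATCGATCTTG,-116.4,9.9,-108.2,9.3,-8.2,1.3,44.6,-10.7,52.8,2.5,-8.2
18,CGCGTACGCGTACGCG,-126.9,6.7,-113.3,6.0,-13.6,1.0,57.9,-16.9,69.8,3.3,-11.9
19,CGCAAGCCGGCTTGCG,-109.4,6.8,-94.6,6.4,-14.8,0.4,64.2,-16.7,72.2,1.9,-8.0
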