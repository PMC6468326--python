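cosolute,id,sequence,dH,dH_err,TdS37,TdS37_err,dG37,dG37_err,Tm
20wt% dextran 70,6a,GATCCGGATC,-72.0,3.3,-63.4,3.2,-8.6,0.15,49.0
20wt% dextran 70,6b,GGATCGATCC,-73.0,2.0,-64.3,1.9,-8.7,0.10,49.1
20wt% dextran 70,7a,ATGAGCTCAT,-66.9,2.3,-59.0,2.2,-7.9,0.10,45.1
20wt% dextran 70,7b,ATCAGCTGAT,-68.5,2.5,-60.8,2.3,-7.7,0.13,45.2
20wt% Ficoll 70,6a,GATCCGGATC,-78.0,1.8,-69.0,1.7,-9.0,0.10,51.5
20wt% Ficoll 70,6b,GGATCGATCC,-79.6,2.2,-70.4,2.0,-9.2,0.14,51.0
20wt% Ficoll 70,7a,ATGAGCTCAT,-66.4,3.0,-58.5,2.9,-7.9,0.12,46.1
20wt% Ficoll 70,7b,ATCAGCTGAT,-68.2,2.3,-60.2,3.2,-8.0,0.11,46.5
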