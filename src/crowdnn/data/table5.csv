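set,dG37,err
AA,-0.56,0.03
AT,-0.37,0.03
TA,-0.28,0.03
CA,-0.80,0.04
GT,-0.84,0.03
CT,-0.66,0.05
GA,-0.86,0.03
CG,-1.27,0.05
GC,-1.40,0.05
GG,-1.06,0.04
init_GC,1.33,0.16
init_AT,1.98,0.67
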