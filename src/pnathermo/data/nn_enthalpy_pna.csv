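term,value,se,p_value
AA,8.65,0.16,
AT,8.28,0.32,
TA,9.34,0.32,
AG,10.64,0.27,
GA,8.91,0.35,
AC,8.90,0.19,
CA,10.31,0.17,
GG,12.32,0.19,
GC,8.69,0.30,
CG,11.71,0.34,
Init,2.27,0.46,
T.GC,1.62,0.35,
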