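channel,metric,before,after
R,contrast,11.38,10.45
G,contrast,11.84,10.76
B,contrast,12.79,9.97
R,homogeneity,0.64,0.72
G,homogeneity,0.64,0.64
B,homogeneity,0.59,0.69
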