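patient_id,metric,channel,before,after
1,homogeneity,gray,0.65,0.68
2,homogeneity,gray,0.58,0.68
3,homogeneity,gray,0.85,0.89
4,homogeneity,gray,0.52,0.74
5,homogeneity,gray,0.52,0.63
6,homogeneity,gray,0.63,0.69
7,homogeneity,gray,0.66,0.71
8,homogeneity,gray,0.58,0.87
9,homogeneity,gray,0.74,0.86
10,homogeneity,gray,0.65,0.87
11,homogeneity,gray,0.66,0.72
12,homogeneity,gray,0.36,0.41
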