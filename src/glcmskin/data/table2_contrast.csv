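patient_id,metric,channel,before,after
1,contrast,gray,8.41,7.65
2,contrast,gray,8.66,7.63
3,contrast,gray,9.68,8.55
4,contrast,gray,7.35,6.32
5,contrast,gray,6.69,6.41
6,contrast,gray,4.56,4.32
7,contrast,gray,7.87,7.02
8,contrast,gray,5.69,4.99
9,contrast,gray,8.37,7.54
10,contrast,gray,6.29,5.98
11,contrast,gray,8.88,7.68
12,contrast,gray,7.54,6.66
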