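patient_id,metric,channel,before,after
1,brightness,gray,165.25,196.35
2,brightness,gray,163.25,175.36
3,brightness,gray,125.36,142.36
4,brightness,gray,184.36,199.36
5,brightness,gray,165.52,175.54
6,brightness,gray,175.21,187.52
7,brightness,gray,136.98,154.23
8,brightness,gray,169.36,180.23
9,brightness,gray,152.52,185.25
10,brightness,gray,145.55,165.32
11,brightness,gray,139.25,174.32
12,brightness,gray,150.63,159.37
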