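treatment,timepoint_h,percent_positive
Control,24,62.1
PGAL 100,24,33.4
PGAL 200,24,22.82
PGAL-His 133,24,33.32
PGAL-His 266,24,26.31
His 33,24,57.51
His 66,24,59.99
Control,48,31.17
PGAL 100,48,9.03
PGAL 200,48,4.81
PGAL-His 133,48,8.23
PGAL-His 266,48,6.07
His 33,48,29.33
His 66,48,29.18
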