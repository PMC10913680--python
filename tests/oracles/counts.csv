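,a1,a2,a3,a4,a5,a6,a7,a8
s1,32,2,34,11,36,11,17,26
s2,5,22,20,31,39,26,16,16
s3,16,32,12,6,13,0,4,3
s4,30,28,27,18,28,6,36,20
s5,37,6,19,27,19,17,6,15
s6,9,12,27,25,24,14,38,3
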