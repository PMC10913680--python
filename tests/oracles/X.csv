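,x1,x2,x3,x4,x5
s1,0.304717,-1.039984,0.750451,0.940565,-1.951035
s2,-1.30218,0.12784,-0.316243,-0.016801,-0.853044
s3,0.879398,0.777792,0.066031,1.127241,0.467509
s4,-0.859292,0.368751,-0.958883,0.87845,-0.049926
s5,-0.184862,-0.68093,1.222541,-0.154529,-0.428328
s6,-0.352134,0.532309,0.365444,0.412733,0.430821
s7,2.141648,-0.406415,-0.512243,-0.813773,0.615979
s8,1.128972,-0.113947,-0.840156,-0.824481,0.650593
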