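,y1,y2,y3,y4
s1,0.743254,0.543154,-0.66551,0.232161
s2,0.116686,0.218689,0.871429,0.223596
s3,0.678914,0.067579,0.289119,0.631288
s4,-1.457156,-0.319671,-0.470373,-0.638878
s5,-0.275142,1.494941,-0.865831,0.968278
s6,-1.68287,-0.334885,0.162753,0.586222
s7,0.711227,0.793347,-0.348725,-0.462352
s8,0.857976,-0.191304,-1.275686,-1.133287
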