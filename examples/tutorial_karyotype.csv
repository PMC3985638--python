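name,length_mb,copies
c0,100,1
c1,100,1
c2,100,1
c3,100,1
c4,100,1
c5,100,1
c6,100,1
c7,100,1
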