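species,pu,amount
s1,A,90
s1,B,10
s2,B,10
s3,B,80
s2,C,90
s3,D,20
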