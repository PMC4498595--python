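id,target,spf,name
s1,80.0,100.0,species one
s2,80.0,100.0,species two
s3,80.0,100.0,species three
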