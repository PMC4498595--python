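id,cost,status,wetland_id,wetland_type,area
A,1.0,0,,lacustrine,2.0
B,1.0,0,,palustrine,4.0
C,1.0,0,,riverine,1.0
D,1.0,0,,reservoir,3.0
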