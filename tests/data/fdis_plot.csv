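species,count,trait
A,3,10
B,1,20
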