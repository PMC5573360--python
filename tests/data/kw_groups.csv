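value,group
1,a
2,a
3,a
4,b
5,b
6,b
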