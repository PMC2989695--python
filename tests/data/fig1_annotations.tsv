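A	6
B	3,4,5
C	7
y	1,2
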