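(((8,9)4,5)2,(6,7)3)1;
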