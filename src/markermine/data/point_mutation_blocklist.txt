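T47D
C33A
A549
H1975
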