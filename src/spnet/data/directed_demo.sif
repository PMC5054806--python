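1	pd	2
1	pd	3
2	pd	4
3	pd	4
4	pd	5
5	pd	2
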