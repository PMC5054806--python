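1	pp	2
1	pp	8
2	pp	3
3	pp	5
3	pp	7
4	pp	9
5	pp	6
5	pp	7
6	pp	8
6	pp	10
7	pp	4
7	pp	8
8	pp	10
10	pp	4
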