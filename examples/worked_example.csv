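time,Y1,Y2
1,0.6,1.5
2,2,1.5
3,0.3,1
4,3.5,4.8
5,0.95,2
6,3.1,4
7,2.4,1.8
8,2.7,2.1
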