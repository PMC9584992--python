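case,mgfr,amdrd,ckdepi_cr,ckdepi_cy,ckdepi_crcy
1,16,34,34,25,29
2,17,13,14,17,14
3,20,12,12,20,15
4,21,24,25,22,23
5,29,19,21,23,21
6,30,38,39,28,32
7,45,33,35,43,38
8,46,56,59,56,57
9,66,109,95,93,97
10,68,49,53,62,57
11,78,60,68,65,65
12,80,116,122,107,114
13,95,55,62,58,58
14,95,115,106,98,103
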