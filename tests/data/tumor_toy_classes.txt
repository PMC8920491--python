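0000000000000000000000000000000000000000
0000000000000000000000000000000000000000
0000000000000000000000000000000000000000
0000000000000000000000000000000000000000
0000000000000000000000000000000000000000
0000000000000000000000000000000000000000
0000000000000000000000000000000000000000
0000000000000000000000000000000000000000
0000000000000000000000000000000000000000
0000000000000000000000000000000000000000
7777711111111111111111111000000000000000
7777711111111111111111111000000000000000
7777711111111111111111111000000000000000
7777711111333333333311111000000000000000
7777711111333333333311111000000000000000
7777711111333333333311111000000000000000
7777711111333333333311111000000000000000
7777711111111111111111111000000000000000
7777711111111111111111111000000000000000
7777711111111111111111111000000000000000
7777755555555555555555555000000000000000
7777755555555555555555555000000000000000
7777755555555555555555555000000000000000
7777755555555555555555555000000000000000
7777755555555555555555555000000000000000
0000000000000000000000000000000000000000
0000000000000000000000000000000000000000
0000000000000000000000000000000000000000
0000000000000000000000000000000000000000
0000000000000000000000000000000000000000
0000000000000000000000000000000000000000
0000000000000000000000000000000000000000
0000000000000000000000000000005555555500
0000000000000000000000000000005555555500
0000000000000000000000000000005555555500
0000000000000000000000000000005555555500
0000000000000000000000000000005555555500
0000000000000000000000000000005555555500
0000000000000000000000000000000000000000
0000000000000000000000000000000000000000
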