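subject,task1,task2,task3,task4
1,32,59,59,74
2,59,65,62,62
3,71,69,69,69
4,55,59,59,60
5,53,59,59,59
6,46,52,49,50
7,60,62,59,59
8,54,62,60,61
9,80,77,79,79
10,65,63,69,71
11,66,66,63,69
12,48,49,49,49
13,51,59,51,57
14,65,63,64,64
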