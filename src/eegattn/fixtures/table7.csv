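subject,accuracy_before,accuracy_after
1,79.2793,84.6847
2,87.8049,89.4309
3,90.7801,91.4894
4,87.2881,86.4407
5,89.7436,90.2655
6,92.9293,97.9798
7,94.2149,98.3471
8,89.8305,90.7563
9,85.2564,86.1635
10,89.7059,93.3824
11,95.4198,94.7368
12,94.9495,97.9798
13,91.8919,91.8919
14,91.3386,94.4882
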