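newly_added,subset,accuracy_pct,retained
F7,F7,84.8,seed
F5,"F7,F5",93.2,yes
F4,"F7,F5,F4",93.7,yes
F1,"F7,F5,F4,F1",94.2,yes
F6,"F7,F5,F4,F1,F6",94.5,yes
F3,"F7,F5,F4,F1,F6,F3",94.3,no
F2,"F7,F5,F4,F1,F6,F2",93.6,no
F10,"F7,F5,F4,F1,F6,F10",90.2,no
F9,"F7,F5,F4,F1,F6,F9",91.6,no
F8,"F7,F5,F4,F1,F6,F8",89.5,no
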