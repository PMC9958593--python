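group,accuracy_pct
F1,83.2
F2,63.4
F3,71.0
F4,84.0
F5,84.4
F6,81.65
F7,84.8
F8,32.1
F9,41.0
F10,43.6
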