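piR-001312
piR-004150
piR-004153
piR-009295
piR-014620
piR-016677
piR-017716
piR-017723
piR-017724
piR-020326
piR-020365
piR-020388
piR-020829
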