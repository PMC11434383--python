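piR-003017
piR-006841
piR-008192
piR-010455
piR-011738
piR-013264
piR-015902
piR-018343
piR-019477
piR-021586
piR-022910
piR-023655
piR-024881
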