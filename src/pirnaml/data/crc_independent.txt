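piR-000335
piR-005132
piR-015481
piR-021520
piR-015551
piR-020980
piR-002587
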