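piR-932
piR-31106
piR-34377
piR-34736
piR-35407
piR-36026
piR-36249
piR-36318
piR-36743
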