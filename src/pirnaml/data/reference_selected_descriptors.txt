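C
C/N
CU
UUC
CGC
5sCAG
5sAAG
5sGGU
5sGGC
5eCA
5eUGA
5eGGA
5eAGG
AGGC
AUCA
GAAA
GAGU
GGCA
GUAG
GUGU
CUUC
UAAA
UCCA
UCCC
UCUG
UUGU
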