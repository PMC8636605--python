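>hp_mixed_89 synthetic 89-bp hairpin stem, blocky GC profile (~49% GC) loop=TTTT
GGGGGGCCTGCTGTCGAATACGCGCGCGGCAGGCGTTTATTACGCCGTTTCTATTACAAG
ATAAAATTATTTAAATAACCGGAGGCCCT
>hp_uniform_89 synthetic 89-bp hairpin stem, uniform GC profile (~51% GC) loop=TTTT
GACTGACTGACTGACTGACTGACTGACTGACTGACTGACTGACTGACTGACTGACTGACT
GACTGACTGACTGACTGACTGACTGACTG
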