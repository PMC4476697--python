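assay,role,sequence
ND4-1,forward,ATAGCCTATCCATTCCTCATGCTTT
ND4-1,reverse,GTGTACTCGTTCATAGTTAGTGTTGG
ND4-1,probe,AGGCATAATCATAACCAGCTC
COI-1,forward,AACTGACTCGTACCGCTAATAATCG
COI-1,reverse,TGAGGATGCCAGAAGTAATAGGAAG
COI-1,probe,CTTTCCACGTATAAACAAC
COI-1A,forward,AACTGACTCGTACCGCTAATAATCG
COI-1A,reverse,TGAGGATGCCAGAAGTAATAGGAAG
COI-1A,probe,CTTTCCACGTATAAACAACA
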