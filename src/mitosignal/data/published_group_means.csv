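group,timepoint,gene,mean,sem,n_animals
RNR-6h,pre,COI-1,0.99,0.16,4
RNR-6h,pre,COI-1A,0.99,0.16,4
RNR-6h,pre,ND4-1,1.24,0.10,4
RNR-6h,post,COI-1,1.99,0.34,4
RNR-6h,post,COI-1A,1.99,0.34,4
RNR-6h,post,ND4-1,2.22,0.44,4
RNR-25h,pre,COI-1,0.68,0.19,4
RNR-25h,pre,COI-1A,0.72,0.21,4
RNR-25h,pre,ND4-1,0.71,0.23,4
RNR-25h,post,COI-1,2.30,0.79,4
RNR-25h,post,COI-1A,2.34,0.80,4
RNR-25h,post,ND4-1,2.44,0.83,4
CCI-25h,pre,COI-1,0.75,0.11,5
CCI-25h,pre,COI-1A,0.75,0.09,5
CCI-25h,pre,ND4-1,0.79,0.11,5
CCI-25h,post,COI-1,1.33,0.25,5
CCI-25h,post,COI-1A,1.29,0.23,5
CCI-25h,post,ND4-1,1.43,0.23,5
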