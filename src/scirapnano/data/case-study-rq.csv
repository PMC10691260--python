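criterion_id,Study 1,Study 2,Study 3,Study 4,Study 5,Study 6,Study 7,Study 8,Study 9,Study 10,Study 11
RQ1,F,F,F,F,F,F,F,F,F,F,F
RQ2,F,NF,NF,NF,F,NF,NF,F,F,F,F
RQ3,F,NF,F,NF,F,F,F,F,F,F,NF
RQ4,F,F,F,F,F,F,F,F,F,F,F
RQ5,F,F,F,F,F,F,F,F,F,F,F
RQ6,NF,F,NF,F,F,F,F,NF,NF,F,NF
RQ7,F,F,F,NF,F,NF,NF,F,F,F,F
RQ8,F,NF,F,NF,F,F,NF,F,F,F,NF
RQ9,F,NF,NF,NF,F,NF,NF,F,NF,NF,NF
RQ10,F,F,F,NF,F,F,NF,F,NF,NF,F
RQ11,NF,F,NF,NF,F,NF,NF,F,F,NF,F
RQ12,NF,NF,NF,NF,NF,NF,NF,NF,NF,NF,PF
RQ13,NF,NF,NF,NF,NF,NF,NF,NF,NF,NF,NF
RQ14,F,PF,F,NF,F,F,F,F,NF,NF,NF
RQ15,F,NF,F,F,F,F,F,F,F,F,PF
RQ16,F,F,F,F,F,F,F,F,F,F,F
RQ17,F,F,F,F,F,F,F,F,F,F,F
RQ18,NF,NF,NF,NF,NF,NF,NF,NF,NF,NF,NF
RQ19,PF,F,PF,NF,NF,NF,NF,NF,NF,NF,ND
RQ20,F,F,F,F,F,F,NF,F,F,F,F
RQ21,F,F,F,F,F,F,F,F,NF,F,F
RQ22,F,NF,NF,NF,NF,NF,NF,NF,NF,NF,NF
RQ23,F,F,F,F,F,F,F,F,F,F,F
RQ24,F,F,NF,NF,F,F,F,F,F,F,ND
RQ25,F,F,F,F,F,F,F,F,F,F,F
RQ26,F,F,F,NF,F,NF,F,F,F,F,F
RQ27,F,NF,PF,NF,F,PF,F,F,F,F,F
RQ28,F,PF,NF,NF,F,F,PF,F,NF,NF,F
RQ29,F,F,F,F,F,F,PF,F,F,F,F
RQ30,F,F,F,NF,F,F,F,F,F,F,F
RQ31,F,F,F,F,F,F,F,F,F,F,F
RQ32,F,F,F,F,F,F,NF,F,F,F,F
RQ33,F,F,F,F,F,F,F,F,F,F,F
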