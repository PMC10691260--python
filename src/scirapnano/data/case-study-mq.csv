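criterion_id,Study 1,Study 2,Study 3,Study 4,Study 5,Study 6,Study 7,Study 8,Study 9,Study 10,Study 11
MQ1,F,PF,PF,NF,F,PF,PF,F,F,F,F
MQ2,PF,PF,F,NF,F,F,F,F,PF,F,PF
MQ3,F,NF,F,NF,F,NF,F,NF,PF,PF,PF
MQ4,F,F,F,F,F,F,F,F,F,F,F
MQ5,F,F,PF,PF,F,F,NF,F,F,F,PF
MQ6,PF,NF,F,NF,F,F,NF,F,NF,NF,NF
MQ7,F,F,F,F,F,F,F,F,F,F,F
MQ8,F,F,F,PF,F,F,F,F,NF,F,F
MQ9,F,F,F,F,F,F,F,F,F,F,F
MQ10,F,PF,PF,NF,F,F,F,NF,F,F,PF
MQ11,F,F,PF,PF,F,PF,NF,F,PF,F,F
MQ12,F,F,F,NF,PF,PF,F,F,PF,PF,PF
MQ13,F,F,PF,F,F,F,F,F,F,F,PF
MQ14,F,F,F,F,F,PF,F,F,F,F,F
MQ15,F,NF,PF,PF,F,F,F,F,F,F,F
MQ16,PF,NF,F,NF,PF,PF,PF,PF,PF,NF,NF
MQ17,F,F,F,F,F,PF,PF,F,F,F,F
MQ18,F,F,F,PF,F,PF,NF,PF,NF,F,F
MQ19,F,F,F,PF,F,F,F,F,F,F,F
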