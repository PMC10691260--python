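criterion_id,Study 1,Study 2,Study 3,Study 4,Study 5,Study 6,Study 7,Study 8,Study 9,Study 10,Study 11
REL1,DR,DR,DR,DR,DR,DR,DR,DR,DR,DR,DR
REL2,DR,DR,IR,IR,IR,DR,DR,DR,DR,DR,DR
REL3,DR,DR,DR,DR,DR,DR,DR,DR,DR,DR,DR
REL4,DR,IR,DR,DR,DR,IR,IR,DR,DR,DR,DR
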