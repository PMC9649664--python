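!Isolation method:	TRIzol/RNeasy/CTAB
Kit lot number:	
DNase treatment:	Yes/No
Operator:	
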