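SampleID	RNA ng per ul	A260-280	A260-230	RIN
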