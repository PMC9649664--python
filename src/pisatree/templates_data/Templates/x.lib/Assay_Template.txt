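!Title:	
Description:	
!Assay class:	wet/dry
Upload to FAIRDOMHub:	Yes
Sharing permission:	Private/Public
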