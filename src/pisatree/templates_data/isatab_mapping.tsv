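# pISA key -> ISA-Tab investigation-file field (flat TSV mapping)
Title	INVESTIGATION	Investigation Title
Description	INVESTIGATION	Investigation Description
Start date	INVESTIGATION	Investigation Submission Date
Creation date	INVESTIGATION	Investigation Submission Date
Principal investigator	INVESTIGATION CONTACTS	Investigation Person Last Name
Institution	INVESTIGATION CONTACTS	Investigation Person Affiliation
Title	STUDY	Study Title
Description	STUDY	Study Description
Start date	STUDY	Study Submission Date
# per-assay-type ISA annotations: @assay <type> <measurement> <technology>
@assay	RNAisol	transcription profiling	nucleic acid extraction
@assay	qPCR	transcription profiling	quantitative PCR
@assay	NGS	transcription profiling	nucleotide sequencing
@assay	Ranalysis	data transformation	computational analysis
@class	wet	material processing	unknown technology
@class	dry	data transformation	unknown technology
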