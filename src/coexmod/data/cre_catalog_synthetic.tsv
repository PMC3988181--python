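accession	consensus	description
S000193	AACCCCC	ACII element; Myb protein binding sites; vascular-specific expression (synthetic consensus stand-in)
S000288	TGAGGGGA	SE1 (stem element 1); vascular expression (synthetic consensus stand-in)
S000306	TCACCCCT	elicitor and light responsive cis-acting element (synthetic consensus stand-in)
S000437	AGGGGGGC	binding site of R2R3-type MYB factor (synthetic consensus stand-in)
S000221	CCCCTCCT	CE3 (coupling element 3); ABA responsive element (synthetic consensus stand-in)
S000192	CCCTCCCT	ACII element; Myb protein binding sites; vascular-specific expression (synthetic consensus stand-in)
S000189	ACCCCTCA	required for phloem-specific gene expression (synthetic consensus stand-in)
S100001	TATAWAW	TATA box core promoter element (synthetic consensus stand-in)
S100002	CCAAT	CAAT box (synthetic consensus stand-in)
S100003	GGTTAA	GT-1 light-responsive box (synthetic consensus stand-in)
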