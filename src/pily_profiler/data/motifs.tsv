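# Shipped motif catalog: name <TAB> pattern <TAB> optional discontinuous tail.
# Pattern notation: one-letter residue = fixed, x = wildcard, A/B = either
# residue (parentheses optional).  Tail notation: residue@lo-hi are 1-based
# offsets from the core start within which the residue must occur; a trailing
# '!' makes the tail required for a hit (default: annotation only).
# The MIDAS site is discontinuous (DxSxS core ... T ... D); the core alone
# sets the flag, the Thr/Asp positions are annotated when found.
motif1	Dx(D/N)xDGxxD
motif2	DxDxNxxxD
motif3	DxD/NxDxxxxxxD/E
MIDAS	DxSxS	T@6-40,D@7-80
RGD	RGD
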