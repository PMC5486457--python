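# Default avian TE taxonomy: class_pattern	name_pattern	te_type	clade
# Ordered; first matching rule wins. Patterns are case-insensitive globs
# matched against repeat_class_family and repeat_name.
SINE*	*	SINE	None
LINE/CR1*	*	LINE	CR1
LINE/R2*	*	LINE	R2
LINE/RTE*	*	LINE	RTE
LINE*	*	LINE	OtherLINE
LTR/ERV1*	*	LTR	ERV1
LTR/ERVK*	*	LTR	ERV2
LTR/ERV2*	*	LTR	ERV2
LTR/ERVL*	*	LTR	ERV3
LTR/ERV3*	*	LTR	ERV3
LTR*	*	LTR	OtherLTR
DNA*	*	DNA	None
RC/Helitron*	*	DNA	None
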