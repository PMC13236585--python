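family_id	level1	level2	level3	origin	function_at_origin
CBM2	DF	NSP	cellulose	plant	structural
CBM2	DF	NSP	hemicellulose	plant	structural
CBM2	DF	NSP	chitin	fungal	structural
GH1	DF	NSP	cellulose	plant	structural
GH1_1	DF	NSP	cellulose	plant	structural
GH1_2	DF	NSP	hemicellulose	plant	structural
GH6	DF	NSP	cellulose	plant	structural
GT2	DF	NSP	hemicellulose	plant	structural
GT2	mucin	O-glycan	core-mucin	animal	structural
PL3	GAG	sulfated-GAG	heparin	animal	structural
CE4	DF	NSP	pectin	plant	structural
CBM5	mucin	O-glycan	core-mucin	animal	structural
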