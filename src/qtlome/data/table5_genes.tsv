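gene	trait
Gpc-B1	Protein content
Gli-A1	Gluten strength
Gli-A2	Gluten strength
Gli-B2	Gluten strength
Gli-B3	Gluten strength
Glu-A3	Gluten strength
Glu-B1	Gluten strength
Glu-B2	Gluten strength
Glu-B3	Gluten strength
Psy-A1	Yellow color
Psy-B1	Yellow color
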