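organ,mass_g
kidneys,299.0
liver,1910.0
spleen,183.0
red_marrow,1120.0
total_body,73700.0
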