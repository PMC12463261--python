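# Curated high-confidence direct mappings for terms the generalized
# matcher cannot resolve: international brands, research codes,
# high-frequency non-standard phrases.  Two tab-separated columns:
# verbatim raw term (case/accent-insensitive), target standardized name
# or concept id.  Consulted before any vocabulary matching.
doliprane	Paracetamol
lcz696	Sacubitril / Valsartan
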