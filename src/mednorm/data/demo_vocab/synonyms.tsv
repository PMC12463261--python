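concept_id	synonym	language
I01	paracetamol	en
I04	hctz	en
I09	mesalazine	en
M01	losartan hctz	en
X01	adriblastina	en
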