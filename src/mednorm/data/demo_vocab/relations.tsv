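source_id	kind	target	label
B01	HAS_INGREDIENT	I01	acetaminophen
B02	HAS_INGREDIENT	I05	adalimumab
B03	HAS_INGREDIENT	I09	mesalamine
M01	HAS_INGREDIENT	I03	losartan
M01	HAS_INGREDIENT	I04	hydrochlorothiazide
M02	HAS_INGREDIENT	I07	sacubitril
M02	HAS_INGREDIENT	I08	valsartan
X01	HAS_INGREDIENT	I06	doxorubicin
I01	HAS_ATC	N02BE	Anilides
I02	HAS_ATC	A10BA	Biguanides
I03	HAS_ATC	C09CA	Angiotensin II receptor blockers, plain
I04	HAS_ATC	C03AA	Thiazides, plain
I05	HAS_ATC	L04AB	Tumor necrosis factor alpha inhibitors
I06	HAS_ATC	L01DB	Anthracyclines
I09	HAS_ATC	A07EC	Aminosalicylic acid and similar agents
I01	HAS_CLASS	ANALG	Analgesics
I02	HAS_CLASS	HYPOGLY	Blood glucose lowering agents
I04	HAS_CLASS	DIUR	Thiazide diuretics
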