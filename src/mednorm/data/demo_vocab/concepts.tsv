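concept_id	preferred_name	term_type	tier
I01	acetaminophen	INGREDIENT	primary
I02	metformin	INGREDIENT	primary
I03	losartan	INGREDIENT	primary
I04	hydrochlorothiazide	INGREDIENT	primary
I05	adalimumab	INGREDIENT	primary
I06	doxorubicin	INGREDIENT	primary
I07	sacubitril	INGREDIENT	primary
I08	valsartan	INGREDIENT	primary
I09	mesalamine	INGREDIENT	primary
M01	Losartan / Hydrochlorothiazide	MULTI_INGREDIENT	primary
M02	Sacubitril / Valsartan	MULTI_INGREDIENT	primary
B01	Tylenol	BRAND	primary
B02	Humira	BRAND	primary
B03	Asacol	BRAND	primary
X01	doxorubicin	INGREDIENT	extended
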