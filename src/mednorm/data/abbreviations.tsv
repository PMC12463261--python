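# Common reported abbreviations expanded once per token (non-recursive).
# Two tab-separated columns: short form, expansion.
hcl	hydrochloride
asa	acetylsalicylic acid
apap	acetaminophen
mtx	methotrexate
vit	vitamin
sr	sustained release
er	extended release
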