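# Curated non-essential terms removed during normalization.
# One term per line; matching is on normalized (lowercase, accent-folded)
# tokens.  Editable: extend for new dose forms, routes or filler words.
# --- dose forms ---
tablet
tablets
tab
tabs
caplet
caplets
capsule
capsules
cap
caps
injection
injectable
drops
cream
ointment
gel
syrup
solution
suspension
patch
spray
suppository
lozenge
# --- strengths and units ---
mg
ml
mcg
g
iu
ui
unit
units
dose
strength
# --- routes of administration ---
oral
orally
iv
intravenous
im
topical
subcutaneous
inhaled
# --- packaging / filler ---
and
with
extra
unknown
unspecified
# --- French equivalents ---
comprime
comprimes
gelule
gelules
gouttes
sirop
creme
pommade
injectable
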