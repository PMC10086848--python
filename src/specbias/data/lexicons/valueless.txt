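valueless
worthless
worthlessness
insignificant
insignificantly
meritless
unimportant
unimportance
unimportantly
deficient
deficiency
insufficient
inferior
substandard
lack
lacks
lacked
lacking
disfavour
disfavours
disfavoured
disfavouring
useless
uselessness
inutility
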