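chicken
chickens
chick
chicks
goat
goats
sheep
lamb
lambs
pig
pigs
turkey
turkeys
cow
cows
calf
calves
duck
ducks
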