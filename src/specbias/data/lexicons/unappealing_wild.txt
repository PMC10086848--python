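snake
snakes
snail
snails
starfish
crocodile
crocodiles
bat
bats
frog
frogs
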