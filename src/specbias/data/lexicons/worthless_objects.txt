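rock
stone
rubble
debris
junk
dust
rubbish
waste
trash
scrap
object
garbage
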