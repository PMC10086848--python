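care
cares
caring
cared
concern
concerns
concerned
concerning
aid
aids
aided
aiding
help
helps
helping
helped
assist
assists
assisting
assisted
sympathy
sympathize
sympathizes
sympathized
sympathetic
sympathetically
compassion
compassions
compassionate
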