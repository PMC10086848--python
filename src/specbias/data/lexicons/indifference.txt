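apathy
apathetic
uncaring
unaffectionate
indifference
indifferent
unconcern
unconcerned
disregard
disregards
disregarded
disregarding
detach
detaches
detaching
detached
neglect
neglects
neglected
neglecting
neglectful
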