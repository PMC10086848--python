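human
humans
person
persons
peoples
people
adult
adults
teenager
teenagers
child
children
kid
kids
man
men
woman
women
lady
ladies
gentleman
gentlemen
boy
boys
girl
girls
guy
gal
baby
babies
infant
infants
toddler
toddlers
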