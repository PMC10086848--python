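value
valuable
valued
valuing
values
appreciate
appreciates
appreciated
appreciating
precious
preciously
priceless
invaluable
important
importance
importantly
worth
worthy
worthiness
significant
significantly
significance
cherish
cherished
cherishes
cherishing
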