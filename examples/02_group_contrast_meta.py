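"""Pool group contrasts across a family of synthetic embedding models.

Generates the default six-group family (seven models with planted shifts
emulating a humans > companion > wild/food animals > objects ordering),
computes Cohen's d for selected group pairs in each model, and pools them
with a DerSimonian-Laird random-effects meta-analysis.
"""

from specbias import default_family_spec, run_recovery

spec = default_family_spec(seed=1)
report = run_recovery(spec)

pairs = [
    ("humans", "companion_animals"),
    ("humans", "appealing_wild"),
    ("humans", "food_animals"),
    ("humans", "unappealing_wild"),
    ("humans", "worthless_objects"),
    ("companion_animals", "food_animals"),
]
print(f"k = {spec.k} synthetic models, DL random-effects pooling")
for pair in pairs:
    m = report.meta[pair]
    print(
        f"  {pair[0]} vs {pair[1]}: d = {m.estimate:+.2f} "
        f"[{m.ci_low:+.2f}, {m.ci_high:+.2f}], Z = {m.z:.2f}, p = {m.p:.4f}, "
        f"I2 = {100 * m.I2:.0f}%"
    )
# d > 0 means the first group's words associate more strongly with the
# positive attribute pole; the CI and Z come from the pooled random-effects
# estimate across the seven models.
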