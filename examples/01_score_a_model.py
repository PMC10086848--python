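"""Score a toy embedding model against a bipolar attribute.

Builds a tiny in-memory model whose geometry is easy to eyeball, computes
each target word's differential association (mean cosine to the positive
pole minus mean cosine to the negative pole) and standardizes the scores
within the model.  Positive scores mean the word sits closer to "good"
language than to "bad" language.
"""

import numpy as np

from specbias import BipolarAttribute, EmbeddingModel, Lexicon, score_model

rng = np.random.default_rng(0)
axis = np.array([1.0, 0.0, 0.0])

words = {
    "good": axis + rng.normal(0, 0.1, 3),
    "nice": axis + rng.normal(0, 0.1, 3),
    "bad": -axis + rng.normal(0, 0.1, 3),
    "nasty": -axis + rng.normal(0, 0.1, 3),
    "person": 0.8 * axis + rng.normal(0, 0.3, 3),
    "child": 0.7 * axis + rng.normal(0, 0.3, 3),
    "rock": -0.5 * axis + rng.normal(0, 0.3, 3),
    "dust": -0.4 * axis + rng.normal(0, 0.3, 3),
}
model = EmbeddingModel.from_pairs("toy", words.items())

attr = BipolarAttribute(
    "valence", Lexicon("pos", ("good", "nice")), Lexicon("neg", ("bad", "nasty"))
)
targets = [
    ("humans", Lexicon("humans", ("person", "child"))),
    ("objects", Lexicon("objects", ("rock", "dust"))),
]

table = score_model(model, targets, attr, policy="exact")
print(f"model={table.model}  attribute={table.attribute}  sd_used={table.sd_used:.3f}")
for s in table.scores:
    print(f"  {s.word:8s} [{s.group}]  raw={s.raw:+.3f}  standardized={s.standardized:+.2f}")
# Human words land near the positive pole (raw > 0), object words near the
# negative pole (raw < 0); standardized scores are raw / within-model SD.
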