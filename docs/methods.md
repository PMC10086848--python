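# Methods

## Model and procedure

The audit treats each embedding model as one "study" of how language
represents target groups. Within a model *m*:

1. **Per-word differential association.** For target word *w* and a bipolar
   attribute with pole word sets *A* (e.g. concern) and *B* (e.g.
   indifference), `s(w) = mean_a cos(w,a) − mean_b cos(w,b)`, with cosines
   computed on the stored vectors (cosine normalizes internally; vectors
   are not re-normalized first) and clamped to [−1, 1] against rounding.
   `s(w) ∈ [−2, 2]`.
2. **Standardization.** Scores are divided by the sample SD (ddof = 1) of
   the raw scores of *all* target words scored in the run for that model
   and attribute — including the worthless-objects benchmark when present —
   with no mean-centering. Any common positive rescaling cancels in
   Cohen's d, so this choice does not affect contrasts; division-only keeps
   the zero point (equal association with both poles) interpretable. The
   divisor is recorded as `sd_used` for reproducibility of standardized
   values.
3. **Group contrast.** Cohen's d between two groups' scores with pooled SD,
   variance `(n1+n2)/(n1 n2) + d²/(2(n1+n2))`. Hedges' small-sample
   correction `J = 1 − 3/(4(n1+n2)−9)` is available behind a flag but off
   by default, because the audit's effect-size convention is plain d.
4. **Pooling.** The k models' d values are pooled with a random-effects
   model: τ² by DerSimonian–Laird (closed-form moment estimator; REML
   optional, maximized numerically and floored at 0), weights 1/(vᵢ+τ²),
   Wald 95% CIs, two-sided normal p, heterogeneity I² = max(0,(Q−df)/Q).
   No Knapp–Hartung adjustment: the reported CIs are symmetric Wald
   intervals paired with Z statistics. k = 1 passes the single estimate
   through with τ² = I² = 0.
5. **Attribute correlation.** Per model, Pearson r between two attributes'
   standardized scores over words scored in both runs (paired by token,
   incomplete pairs dropped, n ≥ 4), pooled on the Fisher-z scale with
   variance 1/(n−3) and back-transformed through tanh. Implemented as
   per-model r pooled meta-analytically; computing a single r over words
   pooled across models would be an alternative reading, but pooling
   per-model estimates matches the rest of the design (models as studies).

### Power

`meta_power` gives the design-stage power of the pooled two-sided Wald
test. The per-model sampling variance v follows from (d, n1, n2); an
anticipated I² is treated as a fixed design parameter converting to
τ² = v·I²/(1−I²), so each model's total variance is v/(1−I²), the meta SE
is √(v/((1−I²)k)), and power = Φ(λ−z_{α/2}) + Φ(−λ−z_{α/2}) with
λ = d/SE. The analytic value is slightly conservative relative to
simulation of the actual DL procedure (which often estimates τ̂² = 0 under
near-homogeneity and hence uses a smaller SE); at the audit's design
(k = 7, n = 8, I² = 20%, d = 0.95) the two agree within about one
percentage point, both ≈ 0.98–0.99.

## Word lookup and attrition

Vector files are read directly (word2vec text with optional header,
word2vec binary, headerless GloVe text; UTF-8). Duplicate tokens keep the
first occurrence with a warning; all-zero vectors are dropped at load (no
direction, no cosine). Default lookup policy is exact-then-lowercase,
because pre-trained vocabularies differ in casing conventions; it is
configurable per run. No subword reconstruction and no query-time
lemmatization: a word without a stored vector is *missing*, counted in the
coverage report, and attribute-word attrition is drop-and-log, never
imputed. A model missing an entire pole (or a whole group) is dropped from
the affected contrast with a warning, shrinking k, rather than aborting
the run.

## Word lists

The packaged lists are data files (one token per line), not code
constants, so other audits can swap them: six target groups (humans 34,
companion animals 10, appealing wild 8, food animals 19, unappealing wild
11, worthless objects 12) and two attributes (concern 29 / indifference
21; value 26 / valueless 25). British spellings are kept verbatim; an
opt-in expansion appends American variants. Tokens are stored lowercase —
the case-insensitive default lookup makes this lossless for the packaged
common nouns.

## Synthetic families

The generator plants a known structure so recovery is checkable: each
model draws a unit attribute axis u; pole-A words sit at γu + ε, pole-B at
−γu + ε, and group-g words at δ_{g,m}·u + ε, with isotropic ε of sd
`noise_sd`. The realized shift δ_{g,m} = δ_g + η_{g,m} with η drawn
independently per group and model at sd `tau_plant`: a shift shared by all
groups would cancel in every contrast, so per-group draws are what plant
between-model heterogeneity in d. Streams are deterministic given
(seed, model_index), with per-model streams at seed + model_index. An
optional second attribute axis at a chosen correlation ρ with the first
induces a between-attribute score correlation.

δ is an axis shift, not a target cosine — the cosine readout is nonlinear
in δ — so validation is framed as sign/ordering recovery, type-I error and
power rather than exact d calibration. Defaults emulate the audit's
conditions: k = 7 models, noise_sd = 0.3, γ = 1, pole size 20, dim = 50
(large enough for generic high-dimensional geometry, small enough that a
thousand-replicate calibration runs in seconds). The default six-group
family uses the packaged list sizes with planted shifts (0.34, 0.26, 0.12,
0.10, 0.06, −0.12) chosen from the empirical gap→d mapping (axis gap 0.2 ≈
pooled d 0.5; 0.3 ≈ 0.8 at these noise settings) so pooled contrasts land
in the d ≈ 0.2–1.4 range typical of embedding-bias audits, with mild
heterogeneity (tau_plant = 0.05) and attribute-axis correlation 0.6.

What the generator does *not* emulate: frequency-dependent vector quality,
anisotropic embedding geometry, polysemy, and vocabulary attrition
patterns of real corpora. Passing calibration therefore shows the
statistical pipeline is sound under its assumptions, not that any
particular real corpus is biased.

## Numerical choices and degenerate inputs

- Cosines clamped to [−1, 1]; zero-norm vectors are errors at the cosine
  level and filtered at load.
- Standardization requires ≥ 2 resolvable target words and non-identical
  raw scores (σ > 0), else the run errors for that model/attribute.
- τ² floors at 0 (DL truncation; REML bounded optimization on [0, ∞)).
- I² is reported as a proportion in [0, 1]; CSV consumers multiply by 100.
- Pooling validates that all contrasts share attribute and group pair;
  correlation pooling requires every n ≥ 4.
- The full-pipeline type-I error at α = .05 with k = 7 runs slightly
  conservative (≈ 4%), the familiar behaviour of DL pooling with estimated
  τ² widening the SE under homogeneity.

## Scope and limitations

The package consumes vector files; training embeddings, corpus cleaning
and lemmatization, WordNet seed expansion of the word lists, per-contrast
permutation tests, multiple-testing adjustment (a Holm option exists but
is off by default, matching the unadjusted reporting convention),
prediction intervals and publication-bias diagnostics are out of scope.
Forest-plot graphics are not reproduced; outputs are CSVs that any
plotting tool can consume. Reproducing the original headline estimates
requires the seven external pre-trained/bespoke models; with those vector
files on disk, the same `specbias run` config drives the identical
pipeline.
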