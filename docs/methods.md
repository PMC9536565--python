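# Methods

This note documents the models and procedures implemented in `lettersim`,
the parameter choices that matter, and what the synthetic validation does
and does not establish.

## Behavioral RDM estimation

**Visual search.** Each session (HIT) measures every unordered letter
pair once under a fixed font, target position, and target–distractor
assignment, so between-observer speed differences load equally on all
pairs.  Reaction times are log-transformed (speeded RTs are positively
skewed and approximately lognormal) and z-scored within HIT; the z-scores
therefore express each pair's relative difficulty inside that session's
own distribution and are invariant to any multiplicative rescaling of a
session's RTs.  Incorrect trials are removed before transformation.
Trials beyond |z| = 3 are removed in a single pass; z-scores are *not*
recomputed afterwards — a deliberate determinism choice, since iterating
exclusion-and-rescoring can cascade on small sessions.  Note an algebraic
constraint worth knowing when testing: with n trials in a session the
largest attainable |z| is (n−1)/√n, so 3-SD outliers can only exist in
sessions of 11+ trials.  The RDM entry for a pair is minus the mean
retained z, making larger values mean "more dissimilar".  Sessions whose
correct trials have zero RT variance are degenerate (z undefined) and are
dropped with a warning; unobserved pairs are flagged NaN, never imputed.

**Categorization.** The signal is the rejection RT of non-match trials.
Per session, pair cells lose their mean when more than half of their
scheduled repetitions were answered incorrectly (at the full design's 8
repetitions: more than 4), and sessions under 90% overall accuracy are
dropped wholesale.  The surviving per-session pair means feed a linear
mixed model, `RT ~ Condition + (1|HIT)`: fixed effects for the 650
ordered-pair conditions, a random intercept absorbing session speed.
Dummy coding uses the first condition in canonical order as reference;
the reference estimate is added back to every coefficient, making the
result reference-invariant (asserted by test).  The two directions of
each unordered pair are averaged, negated, and written to the lower
triangle.  Estimation is REML by default through `statsmodels`' MixedLM;
split-half reliability loops use ML with a relaxed gradient tolerance for
speed.  The optimizer tries lbfgs first and falls back to bfgs/powell,
because lbfgs can hit a singular profiled Hessian exactly when the
random-intercept variance collapses to zero.  With fewer than two
sessions the random intercept is unidentifiable and the model reduces to
ordinary least squares, whose dummy-coded estimates are exactly the
per-condition cell means.

One property of this estimator is easy to misstate: in a balanced design,
adding a constant to all of one session's RTs shifts *every* condition
estimate by offset/n_sessions — uniformly, whatever the variance
components — so the RDM is invariant only up to an additive constant.
All downstream comparisons are rank correlations, for which the constant
is immaterial.

## Noise ceilings

Split-half reliability bounds any model's achievable correlation.  Search
data are split by font: for each equal half-split of the fonts the
per-font pair vectors are averaged into half-RDMs and Spearman-correlated;
the mean over all C(n, n/2) splits (184,756 at 20 fonts; enumeration
double-counts complementary halves harmlessly, since they give identical
correlations) is corrected with the Spearman–Brown formula 2ρ/(1+ρ).
Categorization data are split by measurement: each condition's
per-session means are partitioned into equal halves (one measurement
dropped at random per odd-count condition, per split), an RDM is fit to
each half with the same mixed-model procedure, and the mean split
correlation is corrected identically.  Exhaustive font enumeration is the
default at ≤ 20 fonts; beyond that, seeded sampling.

## Model RDM conventions

Feature activations arrive as one pooled vector per stimulus image
(spatial activation maps are summed per feature, e.g. 256 maps of 13 × 13
become a 256-vector; summation discards retinotopy, which is the
comparison mechanism being modeled).  Two conventions map the
letter × font activation grid to a letter RDM:

* **Search convention** — distances between letters within each font,
  averaged across fonts: observers only ever discriminated same-font
  letters.
* **Categorization convention** — each letter's across-font mean
  activation is its template (the held-in-mind target); distances run
  from font-specific exemplars to templates and are averaged over fonts.
  The one-directional matrix need not be symmetric, so the two directions
  are averaged, mirroring the behavioral direction-averaging.  The
  resulting self-distances (exemplar to own template) are real but unused
  — only the lower triangle enters comparisons — and are zeroed to keep
  the RDM diagonal convention.

Euclidean distance is the default metric; correlation and cosine
distances are available and leave the qualitative results unchanged on
the synthetic stimuli.  Baselines: a purely categorical space (one-hot
letter identity; all same-letter image pairs at 0, all different-letter
pairs at √2 — any metric monotone in same/different gives the same rank
structure) and an intuitive-feature space of 17–18 rated counts (line
orientations, curve openings, intersection orders, termination sides,
diacritics, symmetry, closed space).  Published hand ratings are not
distributed, so `synthetic_intuitive_table` computes the analogous counts
mechanically from this package's own segment-based glyph templates; it is
a clearly labelled stand-in, adequate for exercising the pipeline but not
a reproduction of human ratings.

**Letter-preferring subspaces.** Per feature, a two-sample Welch t-test
compares pooled activations across a letter image set and an object image
set; features with higher letter-mean and p < α are kept.  Welch rather
than pooled-variance because the two image sets differ in size and spread;
the sample unit is the individual image.  Under a null in which both
groups share one distribution the directional filter keeps ≈ α/2 of
features (the two-sided rate halved) — verified by Monte Carlo.  Matched
random subspaces are drawn without replacement from features responsive
to letters but not selected, size-matched to the selected set.

## Inference

Model–behavior correlation is the Spearman correlation of lower
triangles, traced across network stages.  Two feature spaces are compared
by bootstrapping the unordered letter pairs (resampled with replacement;
duplicated pairs enter the ranks as-is), recomputing both models'
correlations per resample.  `max_layer` mode fixes each model's best
stage from the original sample; `layerwise` compares matched stages.  The
reported p-value is the one-sided proportion of resamples in which the
originally better model is not strictly better; ties count against
rejection, and an observed tie reports p = 1.  Because the direction is
chosen from the same sample, this one-sided proportion is uniform on
[0, 0.5] under the null (type-I ≈ 2α at threshold α); a config-gated
two-sided doubling restores nominal calibration and is what the
calibration suite evaluates.  Degenerate resamples (constant behavior
ranks) are skipped and counted.  Per-font comparisons take each model's
maximum stage correlation within each font and apply a paired t-test
across fonts (dof = n_fonts − 1).

Rank correlations are raw, not reweighted and not ceiling-normalized; the
ceiling is reported alongside.  MDS embeddings (metric stress, fixed
seed) are for visualization only.

## Synthetic data

Glyph "fonts" are parametric perturbations — scale, slant, stroke width,
positional jitter — of fixed fourteen-segment letter templates rendered
to binary rasters (default 32 px); no font files are involved and all 26
templates are mutually distinct.  The latent similarity structure is the
mean within-font pixel-space distance, normalized to [0, 1].

Simulated search log-RTs are `baseline + session offset + slope ×
similarity + noise`, with similarity = 1 − normalized dissimilarity, so
raw RTs are lognormally skewed and more similar pairs are searched more
slowly; a small lapse rate injects far-tail RTs and error probability
grows with similarity.  Defaults: baseline 6.35 log-ms (≈ 570 ms),
session offset SD 0.15, slope 0.40, residual SD 0.20, lapse rate 0.005,
error 0.01 + 0.10 × similarity — magnitudes typical of speeded search.
Simulated categorization RTs (ms) are `550 + session intercept (SD 60) +
150 × similarity + noise (SD 120)` on non-match trials, baseline on
match trials, truncated at 150 ms.  The untrained feature hierarchy
applies random 3 × 3 filters, ReLU, and 2 × downsampling per stage,
pooled by spatial summation.

**Validation scale.** The package's validation runs use 6 letters ×
6 fonts × 60 sessions — enough measurements per pair (≈ 60 search trials,
≈ 24 categorization cells) that both pipelines recover the latent
structure well above their target correlations, while mixed-model fits
stay fast.  At this scale the behavioral RDM has only 15 pairs, so
recovery Spearman values are rank-granular: they fluctuate by a few
hundredths across seeds, occasionally dipping below the large-sample
expectation.  The full 26 × 20 × 240 design is available through the same
generators.

**What passing does not show.** The generator encodes exactly the
structure the pipelines assume (lognormal search RTs, additive session
effects, linear similarity-to-RT mapping, homoscedastic noise).  Real
observers violate all of these to some degree — sequential effects,
fatigue, heavy-tailed residuals, similarity structure that varies by
font — so recovery here validates the estimators' correctness, not their
robustness to human data.  Likewise the random feature hierarchy is a
stand-in for untrained networks only; nothing here speaks to trained
feature spaces.

## Numerical conventions

Canonical pair order is row-major over the strict lower triangle
((b,a), (c,a), (c,b), …), used for all serialized pair vectors.  RDMs are
symmetrized exactly ((A + Aᵀ)/2) after a 10⁻⁸ asymmetry check.
Zero-variance rank correlations return NaN with a warning, never a silent
zero.  Spearman–Brown is applied to negative half-reliabilities with a
warning (the formula's intended domain is positive reliabilities).
Seeded operations use `numpy.random.default_rng` throughout and are
bit-reproducible.
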