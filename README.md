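# lettersim

Pipelines for measuring the perceptual similarity of letters from speeded
behavior and comparing it against candidate feature spaces with
representational similarity analysis (RSA).

## The problem

How similar do two letters look?  Two implicit reaction-time tasks answer
this at scale:

* **Odd-one-out visual search** — one target letter among five identical
  distractor letters; search is slower the more target and distractor look
  alike.  Each session (HIT) tests every unordered pair of the 26
  lowercase letters once (325 trials), with target position, font, and
  target–distractor assignment counterbalanced across 240 sessions.
* **Speeded categorization** — a single letter appears and the observer
  answers "is it the target letter or not?"  The time to *reject* a
  non-matching letter indexes its similarity to the remembered target.
  Each session covers 26 of the 650 ordered (target, non-target) pairs in
  two 13-pair blocks of 8 repetitions each (416 trials), and the full
  matrix is estimated with a linear mixed model.

Both tasks yield a 26 × 26 **representational dissimilarity matrix**
(RDM).  Model feature spaces — network layer activations, a purely
categorical one-hot space, hand-rated intuitive letter features — are
turned into RDMs under task-matched conventions and compared with
behavior by Spearman-correlating lower triangles, with bootstrap
resampling of letter pairs for inference and split-half noise ceilings
(Spearman–Brown corrected, 2ρ/(1+ρ)) as the upper bound any model can
reach.

## The core quantities

* Search RDM entry for pair (i, j): −mean over retained trials of the
  within-HIT z-scored log RT (slower search ⇒ more similar ⇒ lower
  dissimilarity).  Incorrect trials and |z| > 3 outliers are excluded.
* Categorization RDM: fit `RT ~ Condition + (1|HIT)` to per-HIT pair mean
  RTs, add the dummy-coding reference estimate back, average the two
  directions of each pair, negate.
* Noise ceilings: mean split-half Spearman correlation (all C(20,10) =
  184,756 font splits for search; seeded random measurement splits for
  categorization), corrected with 2ρ/(1+ρ).
* Model RDMs: within-font pairwise distances averaged over fonts (search
  convention) or exemplar-to-template distances against across-font mean
  activations (categorization convention), on spatially summed feature
  activations.
* Model comparison: bootstrap the 325 letter pairs with replacement,
  recompute both models' correlations per resample, report the proportion
  of resamples in which the nominally better model fails to win.

A synthetic-data module generates everything needed to validate the
pipelines end to end: parametric glyph "fonts" over segment-based letter
templates, a latent pixel-space similarity structure, behavioral trial
tables with lognormal search RTs, per-session speed offsets and
similarity-dependent slowing, and an untrained random feature hierarchy.

## Worked example

```python
import lettersim as ls
from lettersim.design import generate_search_designs
from lettersim.rdm import lower_triangle

glyphs = ls.render_glyphs("abcdef", n_fonts=6, seed=0)
truth = ls.GroundTruth(ls.truth_rdm_from_glyphs(glyphs))
hits = generate_search_designs(5, glyphs.fonts, 2, seed=1, alphabet="abcdef")
trials = ls.simulate_search(truth, hits, seed=2)

norm, report = ls.preprocess_search(trials)
rdm = ls.build_search_rdm(norm, alphabet=list("abcdef"))
rho = ls.spearman_rdm(lower_triangle(rdm), lower_triangle(truth.rdm))

vecs = [(f, lower_triangle(r))
        for f, r in ls.per_font_rdms(norm, alphabet=list("abcdef"))]
ceil = ls.font_splithalf_ceiling(vecs)

stages = ls.simulate_feature_hierarchy(glyphs, 3, seed=3)
model = [(s.stage, ls.search_convention_rdm(s)) for s in stages]
curve = ls.model_behavior_curve(rdm, model)
res = ls.bootstrap_compare(rdm, [("pixels", truth.rdm)], model,
                           kind="max_layer", n=5000, seed=4)
```

This prints (via the surrounding `print` calls):

```
60 HITs, 900 trials; 3.6% errors, 0.12% outliers removed
recovery of latent structure: Spearman rho = 0.929
noise ceiling: mean split-half rho = 0.799, Spearman-Brown corrected = 0.888 (20 splits)
model-behavior curve: {'stage1': 0.564, 'stage2': 0.268, 'stage3': 0.236}
pixel model vs best stage: diff = +0.364, one-sided p = 0.0040
```

Reading it: a 60-session simulated search experiment recovers the latent
letter-similarity structure at ρ = 0.93; its split-half reliability puts
the noise ceiling at 0.89, so the pixel-space model (here the generative
truth, ρ ≈ 0.93) approaches the ceiling while the random feature
hierarchy's best stage reaches only ρ ≈ 0.56; the bootstrap over letter
pairs confirms the pixel model's advantage (p = 0.004).

A `lettersim` command-line tool wraps the same functions
(`design`, `simulate`, `build-rdm`, `ceiling`, `model-rdm`, `compare`);
run `lettersim --help` for options.

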