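# Methods

## Discriminability model

A numerosity *n* heard from a shaken box is represented internally as a
draw from a normal distribution on the log scale with mean log *n* and
common SD σ.  The discriminability of a contrast (l, m) is
d′ = |log l − log m|/σ.  Defaults fix σ = 1 so d′ is reported in
natural-log units; only relative discriminability matters for the
regression slopes, and a different σ or log base rescales d′ and the
fitted slope inversely without changing any test statistic.  d′ is
computed as log(max/min) of the pair, which makes contrasts with equal
ratios (2:1 and 4:2) bitwise-identical in d′ so rank ties are exact.

Ideal two-alternative forced-choice accuracy is Φ(d′/√2), the
equal-variance ideal observer: chance (0.5) at d′ = 0, strictly
increasing, asymptoting at 1.

Two heuristic difficulty models are registered alongside d′: the absolute
difference |l − m| and the negative ratio −min/max.  All three scores are
oriented so larger = easier, and the identical pair is the hardest case
under each.  The negative ratio is a strictly monotone transform of the
ratio that also determines d′, so the two produce identical contrast
orderings; the absolute difference genuinely disagrees (it calls {9,5}
easier than {2,1}, while d′ orders them the other way).  When used as
regression predictors, every score is negated so that the predictor
increases with difficulty and fitted slopes are positive.

## Synthetic cohorts

The generator emulates the free-exploration design: four experiments, four
numerosity contrasts each, 24 children per experiment, one shaking trial
per contrast.  For child *i* on contrast *c* in position *j* (1–4), the
expected normalized playtime is

    1 + θ·(−d′(c) − mean_k(−d′(c_k)))
      + β_order·(j − 2.5) + β_content·(hidden − mean_k hidden_k)

with defaults θ = 0.24, β_order = −0.051, β_content = 0 (the calibrated
effect sizes on the normalized scale).  All terms are centered within the
child's four trials, so expected normalized playtimes sum exactly to 4 per
child.  Raw seconds are `base_playtime_s · exp(b_i) · max(0.05, expected +
ε)` with a per-child lognormal baseline (b_i ~ N(0, child_sd²), default
0.5), trial noise ε ~ N(0, noise_sd²) on the normalized scale (default
0.15; a multiplicative lognormal variant is available via
`noise_scale="log"` since the noise process of real playtimes is unknown),
and a 0.05 floor that keeps playtimes strictly positive.  Correctness is
Bernoulli with logit p = β₀ + β₁·d′, defaults β₀ = 0 (chance at d′ = 0,
the ideal-observer anchor) and β₁ = 1.12.  Ages are drawn uniform on 4–9
years and have no generative effect.

Trial order follows a Williams 4×4 Latin square cycled over children, so
each contrast occupies each position equally often and order is orthogonal
to difficulty.  The hidden alternative alternates by
(child_index // 4 + contrast_index) mod 2, which is exactly balanced and
orthogonal to the Latin-square rows.  One experiment ("exp6") reproduces
the fixed-content design: every pair contains an 8 or a 3 and that count
stays in the box for all children, providing the within-experiment
dissociation of content from contrast.

### Default contrast sets

The exact experimental contrasts are not fully public, so the default 16
pairs are a documented, fully configurable placeholder chosen by
exhaustive search (over all pairs of counts 1–9) with three properties:

1. each experiment's four max/min ratios have product exactly 36, so all
   four experiments share the same mean d′ (ln 36/4 ≈ 0.90).  Because the
   generator centers −d′ within each child (equivalently within each
   experiment), equal set means make the pooled condition means exactly
   linear in −d′ and the pooled OLS slope an unbiased estimate of θ with
   no between-experiment attenuation;
2. the mean hidden count per contrast is essentially uncorrelated with
   centered −d′ across the 16 contrasts (|Σ mh·x| ≈ 0.09), so the simple
   regression of playtime on hidden count has true slope ≈ 0 and the
   content-null analysis is a genuine null;
3. the difficulty range spans the design's extremes (hardest 9-vs-8,
   d′ = 0.12; easiest 9-vs-1, d′ = 2.20).

The sets are: exp4 {2:1, 4:1, 3:2, 6:2}, exp5 {5:1, 4:2, 9:3, 6:5},
exp6 {3:1, 8:1, 4:3, 9:8} (hidden fixed at 3, 8, 3, 8), exp7 {9:1, 5:3,
9:5, 8:6}.  No analysis depends on the specific pairs beyond this spread.

Forced-choice cohorts are i.i.d. Bernoulli choices; the default designs
mirror the three box-choice experiments (n = 16 with p = 13/16, n = 24
with p = 19/24, n = 24 with p = 18/24).

### What the generator does not emulate

No acoustics, motor behavior, or reaction-time structure; no
heavy-tailed or autocorrelated playtime noise; no age effects; no
child-level heterogeneity in θ.  Passing recovery tests therefore shows
the inference pipeline is consistent and calibrated under the assumed
generative structure, not that real children satisfy it.

## Estimation

Playtimes are normalized per child (trial count × playtime / child total);
children with zero total playtime cannot be normalized and are excluded
with a warning.  The default estimator is trial-level OLS with
cluster-robust (by child) standard errors and its t-based 95% CI; since
the normalization removes per-child intercepts, clustering is the minimal
correction for within-child dependence.  A per-child random-intercept
mixed model (`estimator="mixed"`) is provided as a sensitivity option,
and the untransformed log-playtime response (`playtime_scale="log"`) as
another.  Note that on the normalized scale any purely between-child
predictor (such as age) has an exactly zero coefficient by the
normalization identity; substantive age analyses should use the log
scale.

Accuracy is a logistic regression of trial correctness on d′ with
child-clustered SEs; perfect separation (e.g. every response correct) is
reported as a flagged non-converged fit rather than raised.  Condition
means are per-(experiment, contrast) means of normalized playtime,
correlated with −d′ (Pearson, Fisher-z CI).  Individual slopes are
per-child OLS of normalized playtime on −d′ (positive = longer play on
harder contrasts); children with constant d′ are excluded with a warning,
and the positive-slope proportion gets a binomial CI.

Forced-choice proportions use either the normal approximation
p ± 1.96·√(p(1−p)/n) with bounds clipped to [0, 1] — z is fixed at 1.96
rather than re-derived, for bit-reproducibility of the published-style
intervals — or the exact Clopper–Pearson interval, which needs no
clipping.  Both are offered because published intervals of this kind mix
the two conventions.  At p ∈ {0, 1} the normal interval is zero-width and
flagged degenerate.  The test against chance is the exact two-sided
binomial test under the "minlike" convention (sum of all outcomes no more
likely than the observed one).  Displayed bounds round half-up to two
decimals.

Model comparison fits each (negated) difficulty score to the same
observation set and reports condition-mean Pearson r, trial-level R², AIC
from the Gaussian likelihood on the normalized scale (matching the OLS
estimator), and Spearman rank agreement of the model's contrast ordering
with d′'s.

## Numerical and design choices

- Ranking ties break by smaller max count, then smaller min count, for
  reproducible output.
- Determinism: a single `numpy` Generator seeded from the config drives
  all draws in a fixed order; identical (config, seed) reproduces every
  CSV byte-identically.  Choice-table seeds are derived from the master
  seed.
- Problem sizes: the standard cohort is 96 children (384 trials), matching
  the experimental scale; calibration checks run 200 such cohorts;
  logistic recovery uses 5000 children (20 000 trials), enough to pin the
  accuracy slope to a few percent.
- Degenerate inputs: constant predictors and zero-variance condition means
  raise typed errors; a single-child table falls back to conventional SEs
  with a flag instead of failing.

## Known limitations

The published per-experiment CI conventions are internally inconsistent
(some match the normal approximation, some look exact), so no attempt is
made to reproduce every printed bound — both methods are exposed instead.
σ is fixed rather than estimated from psychophysical data; an empirically
calibrated discriminability scale would change slope magnitudes but not
orderings.  The mixed-model option estimates only a random intercept, not
random difficulty slopes.
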