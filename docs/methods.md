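# Methods

## Data model and assumptions

The pipeline's currency is a dense proteins × samples matrix of NPX values
with a missing-value mask.  NPX is a relative abundance unit on a log2
scale, so differences of NPX values are log2 fold changes and no
re-exponentiation happens anywhere.  Sample annotations carry the trial
structure (subject, arm, timepoint) and optional clinical covariates.
There is **no imputation**: each contrast uses, per protein, the complete
observations (unpaired) or complete subject pairs (paired) available to it,
and proteins falling below the minimum (2 observations per group, or 2
complete pairs) are dropped from that contrast with a logged reason.
Subjects missing one timepoint are excluded from paired contrasts only.
LOD/QC columns are read and carried along but do not filter data: NPX
quality control is assumed to have happened upstream, in the platform's
own normalization.

## Differential expression

Ordinary statistics per protein and contrast:

* unpaired — effect = difference of group means, pooled two-sample
  variance, `d = n_A + n_B − 2`, unscaled SE `u = sqrt(1/n_A + 1/n_B)`;
* paired — effect = mean within-subject (post − pre) difference, sample
  variance of the differences, `d = n_pairs − 1`, `u = sqrt(1/n_pairs)`.

Paired contrasts are one-sample tests on within-subject differences.  For
a balanced two-timepoint design with complete pairs this is algebraically
identical to a subject-blocked linear model, which is why no separate
"blocked" code path exists.

The empirical-Bayes prior `(d₀, s₀²)` is fitted per contrast (each
contrast has its own residual structure) by method of moments on
`e_g = log s²_g − ψ(d_g/2) + log(d_g/2)`, where ψ is the digamma function:
the model implies `E[e_g] = log s₀² + ψ(d₀/2) − log(d₀/2)` and
`Var[e_g] = ψ′(d_g/2) + ψ′(d₀/2)`, so the excess of the empirical variance
of `e` over the mean `ψ′(d_g/2)` term identifies `d₀` through a trigamma
inversion (bracketed Brent root-find, xtol 1e-12) and the mean then gives
`s₀²`.  A non-positive excess means the observed variances are no more
dispersed than pure sampling noise: `d₀ = ∞`, every protein is tested
against the common `s₀² = exp(ē)` with a normal reference.  Zero-variance
proteins are excluded from the moment fit (their log is undefined) but
still tested — shrinkage gives them a positive posterior variance.  This
is the same hierarchical model and estimator used by the standard R
implementation of moderated tests, and the test suite pins our output to
that implementation at 1e-6 on a shared dataset.

Degenerate limits, both exercised in tests: `d₀ = 0` reproduces the
classic t-test exactly; `d₀ = ∞` is the common-variance z-test.

DEP classification supports two rules, both always reported:
`p_only` (p < α, the rule used for screen membership) and `p_and_fc`
(additionally |log2FC| > 0.5, the volcano-labelling convention).  The two
rules genuinely diverge and the choice is the single most consequential
ambiguity in this class of analysis; `p_only` is the default because the
screen is defined on significance alone.  Inequalities are strict on both
sides: p exactly equal to α is neither significant nor eligible for the
"no baseline difference" criterion (such ties are logged).
Benjamini–Hochberg q-values are reported within each contrast but do not
drive screen membership by default.

## The orthogonal screen

Six contrasts; G1 (T2 vs C1) and G2 (C2 vs T1) are descriptive only.  The
screen consumes G3, G4, P1, P2 and builds Sets 1–5 and the core as
described in the README.  The identity `core = (set1 ∩ set3) \ set2` is
enforced by construction and verified exactly on 1000 random membership
configurations.  The screening universe is the intersection of proteins
tested in all four constituent contrasts; anything dropped anywhere is
excluded and logged.  The core is *not* monotone in α (raising α can eject
a protein via the Set-2 criterion); a constructed example in the tests
demonstrates this.

## Synthetic cohorts

The generator draws

```
NPX[g,s,t] = μ_g + u[g,s] + β_g·A_s + γ_g·P_t + δ_g·A_s·P_t + ε,
u ~ N(0, τ²),  ε ~ N(0, σ²)
```

with protein classes null (all effects 0), treatment-specific (δ only),
time-dependent (γ only), baseline-shifted (β only) and mixed (γ and δ).
The mixed class exists specifically to verify that the Set-2 exclusion
removes time-confounded proteins from Set 4.

Defaults emulate the target trial geometry: 22 + 22 subjects, two
timepoints, 92 proteins, and class counts 67 null / 10 treatment-specific
/ 10 time-dependent / 5 mixed.  Effect sizes are in NPX (log2) units:
δ = 1.0, γ = −0.8, β = 0.7, subject SD τ = 0.5, residual SD σ = 0.4,
baseline means μ_g uniform on [2, 10].  The emulated study reports no
usable effect-size estimates, so these are chosen as plausible targeted-
panel magnitudes that give a well- but not perfectly-powered paired
contrast at n = 22 (paired t ≈ 8 for δ = 1.0; the G3/P2 "pass" events then
dominate the core's recovery rate, ~0.9).  Effect signs are drawn ±1 per
protein unless `random_signs=False`.

Clinical scores are linear read-outs
`round(clip(a₀ + Σ_g w_g·NPX[g,s,t] + noise, lo, hi))` on the integer
NIHSS (0–42) and ESRS (0–9) scales, with the intercept solved so the
noise-free score sits at a configurable scale centre (defaults 8 and 4 —
moderate-deficit, moderate-risk).  Negative default weights plant the
higher-protein ↔ milder-deficit pattern.  Rounding happens after noise.

All randomness flows from one seed through two documented sub-streams
(cohort, then scores), each with a fixed draw order, so a seed pins the
cohort bit-for-bit.

What the generator does **not** emulate — and therefore what passing tests
cannot certify about real data: LOD censoring, plate/batch effects,
non-Gaussian noise, heteroscedastic proteins, correlated protein modules,
dropout/missingness patterns, and ESRS's real time-constancy within
subject (scores are generated per timepoint).  Recovery results certify
the screen's logic under its own assumptions, not its field performance.

## Clinical associations

Spearman ρ with average-rank ties; p from the t-approximation on
`ρ·sqrt((n−2)/(1−ρ²))`.  The default scope pools the treatment arm's
baseline and post observations into one correlation per protein — this
treats a subject's two visits as independent observations, which mirrors
the emulated analysis but is not a statistical endorsement; a
per-timepoint scope is available.  Constant inputs or n < 3 yield NA
records that never count as significant.  Sex comparisons default to
Mann–Whitney (robust at ~4–18 per sex; Welch t by config) with BH across
the panel at each timepoint.

## Forest importance

An explicit bagging loop over scikit-learn CART trees (500 trees,
sqrt-mtry, the conventional defaults of the classic forest package):
per-tree bootstrap indices are drawn from the package's own seeded
generator, so each tree's out-of-bag sample is known exactly.  Mean
decrease in accuracy is the unscaled drop in OOB accuracy under
per-feature permutation, averaged over trees (one stacked predict call per
tree keeps this fast); mean decrease in Gini is the per-tree total
impurity reduction attributed to the feature.  The classification target
defaults to timepoint (pre vs post) within the treatment arm — the most
natural reading for ranking treatment-responsive proteins — with arm as a
config alternative.  Ties in either measure break by feature order,
deterministically.

## Enrichment

Exact hypergeometric upper tail `P(X ≥ k)` via the survival function at
k − 1 (exact on integer support).  The default background is
annotation-restricted — panel proteins carrying ≥ 1 annotation in the
loaded GMT collection — which keeps the urn well-defined; full-panel
background by flag.  Venn membership of the intersectional comparison uses
raw p < α (q is always reported alongside); region rows are ordered
all-shared first.

## Problem sizes and numerical checks

The validation suite uses: 500 random small datasets for the classic-t
limit (agreement ≤ 1e-10, measured ~1e-15); every hypergeometric urn with
N ≤ 30 against exact integer enumeration (≤ 1e-12); 1000 random p-vectors
against a hand step-up oracle; prior recovery at d₀ = 4, s₀² = 1,
G = 2000, d = 40 over 20 seeds (d₀ within 20%, s₀² within 10%); 1000
pure-null cohorts for type-I calibration; 50 default-parameter cohorts for
screen recovery (pooled sensitivity ≥ 0.8, time-dependent leakage ≤ 0.05);
1000 random membership configurations for the core identity; and 20 seeded
forest runs for separator dominance.

One calibration subtlety: within a null cohort, all proteins share one
estimated shrinkage prior, so per-protein rejections are weakly correlated
and the independent-Bernoulli (binomial) band understates the Monte-Carlo
noise of a pooled rejection fraction.  The calibration test therefore
treats per-cohort fractions as the independent units and uses their
empirical standard error at the 99% level — the clustered analogue of the
binomial band, which it reduces to when the correlation vanishes.  At 1000
cohorts this band is ~±0.002 around 0.05; the measured paired-contrast
rate is ≈ 0.049 (a very slight conservativeness inherent to fitting d₀ on
a 92-protein panel whose true variances are homogeneous; the reference R
implementation shows the same rate on identical data).

## Known limitations

* No covariate adjustment (age/sex) in the contrasts; no variance-trend or
  robust variants of the moderation.
* The pooled correlation scope double-counts subjects by design (see
  above).
* Replication of the emulated study's printed counts depends on that
  study's unstated analysis settings (membership rule, correlation scope);
  the `replicate` verb therefore reports computed-vs-published tables
  under both membership rules rather than asserting one.
* GMT collections are user-supplied; term-count results depend on the
  annotation version and are intentionally out of validation scope.
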