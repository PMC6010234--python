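# Methods

This note documents the statistical procedures, the modelling assumptions,
the defaults and the numerical choices made in `freelists`, in the spirit of
a model-documentation page: enough detail to audit any number the package
produces.

## Data model and normalization

A dataset is an ordered sequence of respondent lists for one topical
domain.  Order matters twice: respondent order is the axis of the
accumulation analysis (stored order = interview order is the contract — the
package never reorders respondents, because reordering to best fit a
declining curve biases the saturation point downward), and within-list rank
is the input to the rank-weighted salience indices.

Label normalization is deliberately minimal: case-fold, trim, collapse
internal whitespace, then an optional user-supplied synonym map (applied
after normalization, chains resolved, cycles rejected).  No stemming or
fuzzy matching: merging "grapefruit"/"grape fruit" automatically would
silently change unique-item counts, which are the response variable of the
whole analysis.  Within-list duplicates keep the earliest rank.  Ranks and
respondent positions are 1-based.

Empty lists are legal and count toward N: prevalence and both salience
indices are proportions of *people interviewed*, not of non-empty lists.

## Salience

For item i with frequency F_i (lists containing it), mean within-list rank
mR_i, and N respondents:

* prevalence p_i = F_i / N;
* Smith S_i = (1/N) Σ_j (L_j − R_ij + 1)/L_j over lists j containing i;
* Sutrop T_i = F_i / (N · mR_i).

Both indices are bounded above by prevalence, with equality exactly when
the item is always listed first; the suite asserts this on random data.
Index inter-correlations (Spearman and Pearson) are computed after dropping
items mentioned once (`min_frequency = 2` default), because a single rank
observation makes the indices degenerate; aggregated correlations across a
corpus are unweighted means over examples.

The *salient set* of a dataset is the set of items with prevalence ≥ 20% in
the first 20 respondents with full listing.  Both constants are arguments;
the defaults reflect that a 20-person full-listing sample is a realistic
reference study, and 20% prevalence separates core items from the long
tail.  Capture proportions compare that fixed full-listing reference set
with what a smaller and/or truncated design observes; the reference is
never re-derived from truncated lists, since the point of the comparison is
what limited probing loses relative to what full listing shows to matter.

## Accumulation and saturation

The new-item series Y(x) counts items first observed at respondent position
x; its sum is the number of unique items, and its cumulative sum the
accumulation curve (both checked against a brute-force prefix set-union
oracle in the tests).

Four regressions of Y on x are fitted:

| family             | link     | estimator                              | k in AIC |
|--------------------|----------|----------------------------------------|----------|
| normal             | identity | OLS                                    | 3        |
| Poisson            | log      | GLM/IRLS                               | 2        |
| negative binomial  | log      | joint ML (NB2); moment fallback        | 3        |
| negative binomial  | identity | profile likelihood over the dispersion | 3        |

AIC is computed as 2k − 2·loglik with k counting the NB2 dispersion and the
OLS residual variance.  The NB-log dispersion is estimated by joint maximum
likelihood; if the optimizer fails, a moment estimate
(Σ[(y−μ)² − μ]/Σμ²) is substituted and the fit is annotated.  The
NB-identity fit profiles the GLM log-likelihood over the dispersion with a
bounded scalar search (dispersion in [1e-8, 1e4]), starting IRLS from the
OLS line (or a flat positive line if OLS dips non-positive on the observed
range, since an identity-link NB mean must stay positive).  Fit failures
are recorded as non-converged candidates with infinite AIC, never raised.
Model selection takes the minimum AIC among converged candidates with a
fixed tie-break order (NB-log, Poisson-log, NB-identity, normal-identity).
A non-significant slope does not disqualify a fit: the saturation point is
still solved and the slope p-value reported alongside.

Saturation: the threshold rule solves E[Y|x] = threshold (default 1.0 new
item per person; 2.0 is the conventional liberal variant) for continuous x
— `(ln th − b0)/b1` under the log link, `(th − b0)/b1` under identity —
and takes the ceiling, flooring at 1 when even the first respondent is
predicted at or below threshold.  The continuous solution is reported to
2 decimals.  A non-negative slope means the curve never declines to the
threshold and saturation is reported as "not reached" (None), not as an
error.  Slopes within 1e-10 of zero are treated as flat: an exactly
constant series can fit with slope −1e-16 and would otherwise yield an
astronomically distant, meaningless crossing.

Domain sizes: D_SAT sums the fitted means over x = 1..N_SAT without
per-term rounding.  D_TOT under the log link is the geometric tail
exp(b0)·r/(1−r) with r = exp(b1) (verified in the tests against numeric
summation to 10^6 terms at 1e-6 relative tolerance).  Under the identity
link predictions are clamped at zero and summed to the zero crossing; this
is the natural finite analogue, since an identity-link line has no
convergent infinite sum.

Thresholds behave monotonically (a more liberal threshold saturates no
later, and accumulates no more items) and the suite asserts this.

## Capture–recapture

The capture-frequency spectrum f_1..f_t (f_j = items on exactly j lists)
satisfies Σ f_j = S (observed items) and Σ j·f_j = total mentions; both
identities are asserted against a per-item counting oracle.

Closed-population estimation fits Poisson log-linear models to the
spectrum with offset log C(t, j):

    log E[f_j] = log C(t,j) + b0 + b1·j + b2·η_j

with η the heterogeneity column listed in the README (η_0 = 0 in every
model, so the unseen count is always f0 = exp(b0)).  The gamma shape
defaults to 3.5 and is configurable.  Empty frequency classes (f_j = 0)
stay in the fit as zero counts — they are informative for the loglinear
shape.  AIC is 2k − 2·loglik with k the number of regression coefficients.

Chao's lower bound deserves a note.  Its loglinear formulation gives every
class j ≥ 3 its own free term, so those classes are reproduced exactly and
only the singleton and doubleton classes constrain (b0, b1); the model
therefore reduces algebraically to the two-point solution
f0 = f1²(t−1)/(2·t·f2), which the package computes in closed form.  (A
dummy coefficient for an *empty* class j ≥ 3 has no finite MLE, so running
the full IRLS with explicit dummies only adds numerical noise around the
same limit; the tests nonetheless confirm the closed form against an
independent IRLS fit of the two informative classes.)  Its AIC uses the
saturated log-likelihood over non-empty classes with k = 2 plus one per
non-empty class beyond the doubletons.  Degenerate cases: no singletons →
f0 = 0 (nothing suggests unseen mass); no doubletons → the bias-corrected
moment form f1(f1−1)/2 · (t−1)/t, flagged in the estimate's notes.

Model screening fits M0 and the four Mh variants and selects by AIC among
converged fits.  Respondent-heterogeneity models (Mt, Mth) are not
implemented: with the 2^t occasion-pattern table they require, they are
only computable as small-sample screens, and the pipeline's reported
estimates use item heterogeneity only, which is where the salience signal
lives.  Standard errors are not reported; the point estimates are the
deliverable and a delta-method SE would suggest more precision than the
model-selection step justifies.

Directional behaviour established by the test suite: abundance ≥ S always;
M0 point estimates cover the truth on homogeneous simulations (coverage
check over 100+ replicates); on long-tailed (Zipf) data M0 fails or loses
the AIC race to an Mh variant and heterogeneity-aware estimates exceed the
homogeneous one; gamma-model estimates exceed Chao's lower bound on
singleton-heavy spectra.

## Truncation experiment

`truncation_experiment` composes the pieces: truncate to k (default 3)
responses, recompute unique-item yields at n = 10 and 20, refit the
saturation model on the truncated series, and measure salient capture at
(full, n=10), (k, n=20), (k, n=15), (k, n=10) against the full-listing
salient set.  Datasets with fewer than 20 respondents produce a partial
report without the capture fields.  Corpus summaries use medians and ranges
for saturation points and unweighted means for capture proportions.  The
"bits of information" heuristic (mean list length × n) is carried in the
report as a design-comparison aid, not a model quantity.

## Synthetic generator

The generator emulates the statistical structure free-list analyses assume:
a finite domain of D items with strictly positive salience weights (Zipf
i^(−s) by default, or i.i.d. gamma), respondent list lengths from a
lognormal (default) or negative binomial law (rounded, floored at 1,
capped at D), and within-list order by successive weighted sampling without
replacement — drawn in one pass with the Gumbel-key construction, which is
distributionally identical to sequential renormalised sampling.  Defaults
(D = 200, N = 40, Zipf s = 1, lognormal mean 15 with σ = 0.45) sit in the
middle of the ranges typical of published free-list studies: domains of
50–1000 items, 20–100 respondents, mean list lengths 6–35 with roughly
2–4× person-to-person spread.

What the generator reproduces: long-tailed item frequency distributions,
prevalence tracking salience, earlier mention of higher-salience items (a
weak effect conditional on inclusion — the tests assert its direction, not
a magnitude), respondent length variation, and descending concave
accumulation curves.  What it does not: semantic clustering within lists
(runs of related items), respondent-level salience differences beyond list
length (no Mt-style signal), prompting effects, response errors and
synonyms.  Passing recovery tests on synthetic data therefore validates
the estimators under the model's own assumptions; they cannot certify
variant-merging or interviewer effects in real corpora.

The generator is fully deterministic given its seed; replicate seeds in
the recovery suite are spawned from the spec seed via `SeedSequence`.

## Problem sizes and determinism

The test suite and the acceptance script run simulations at deliberately
modest sizes — domains of 40–700 items, 10–55 respondents, 10–120
replicates per property — chosen so the full battery completes in well
under a minute while keeping the Monte-Carlo checks comfortably away from
their assertion boundaries.  All analysis outputs are deterministic
functions of the input data and configuration; randomness enters only
through generator seeds, which are always explicit.

## Known limitations

* The accumulation models are two-parameter curves; domains whose new-item
  series plateaus and then drops (batch effects, mixed administration
  modes) are fitted only in an average sense.
* D_TOT from the identity link depends on the clamp-and-sum convention;
  identity-link extrapolation is inherently less principled than the
  geometric tail and is reported only when that model wins the AIC race.
* AIC comparability across families relies on the stated k conventions;
  other software may count parameters differently and select differently
  in borderline cases.
* The Chao AIC convention (saturated likelihood with per-class terms)
  makes it win ties against smooth Mh models on spectra it fits exactly;
  this mirrors its role as a conservative default.
* Re-ingesting a raw deposited corpus can differ from a published analysis
  by a few unique items per example wherever the original variant-merging
  decisions (synonym handling) were manual and undocumented.
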