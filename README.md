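# freelists

Saturation, salience, and domain-size analysis for free-list interview data.

Free listing is a standard elicitation method in cultural domain analysis,
ethnobiology, public health and qualitative research: each respondent names,
in order, all the items they can think of in a topical domain ("name all the
fruits / illnesses / holidays you can think of").  Two questions dominate
study design: **how many interviews are enough** (thematic saturation), and
**how much does probing depth matter** (full listing versus a few responses
per person)?  This package implements the quantitative machinery to answer
both from the data themselves, for researchers who collect or reanalyse
free-list corpora.

## What it computes

**Salience.**  Per-item prevalence `p = F/N`, mean rank, and the two
standard rank-weighted salience indices:

- Smith: `S_i = (1/N) * Σ_j (L_j − R_ij + 1) / L_j` over lists `j`
  containing item `i` (list length `L_j`, 1-based rank `R_ij`);
- Sutrop: `T_i = F_i / (N · mR_i)` with `mR_i` the item's mean rank.

Both are bounded above by prevalence and equal it exactly for an item always
mentioned first.

**Saturation.**  Walking respondents in interview order gives the new-item
series `Y(x)` = items first mentioned by the `x`-th respondent.  Four count
regressions are fitted — normal-identity (OLS), Poisson-log, negative
binomial-log, negative binomial-identity — and compared by
`AIC = 2k − 2·loglik`.  The saturation point `N_SAT` is the smallest integer
`x` with predicted `Y(x) ≤ 1` (or any other threshold); the domain size at
saturation `D_SAT` sums predictions to `N_SAT`; the total domain size
`D_TOT` extrapolates the log-link geometric series
`exp(b0)·r/(1−r)`, `r = exp(b1)`.

**Domain size with salience heterogeneity.**  Treating respondents as
capture occasions and items as individuals, the capture-frequency spectrum
`f_j` (items on exactly `j` of `t` lists) feeds log-linear closed-population
models `log E[f_j] = log C(t,j) + b0 + b1·j + b2·η_j`: homogeneous (M0) and
item-heterogeneity (Mh) variants — Chao's lower bound, Poisson, Darroch
log-normal, gamma.  The unseen mass is `f0 = exp(b0)` and the domain size
`S + f0`.

**Truncation experiments.**  Re-running everything with lists cut to the
first `k` responses (default 3) quantifies what limited probing loses:
saturation arrives much earlier, but far fewer of the *salient* items (those
with prevalence ≥ 20% in a 20-respondent full-listing reference) are
captured at any fixed sample size.

**Design calculators.**  Under item independence, an idea of prevalence `p`
is seen at least once in `n` interviews with probability `1 − (1−p)^n`;
the inverse gives the minimal `n` for a target confidence.

**Synthetic data.**  A seeded generator draws free lists from a known finite
domain with Zipf or gamma salience weights and lognormal or negative
binomial list lengths, ordering each list by successive weighted sampling
without replacement — so every stage of the pipeline can be validated
against ground truth.

## Worked example

```python
>>> import freelists as fl
>>> spec = fl.DomainSpec(domain_size=120, n_respondents=36,
...                      salience_law=("zipf", 1.0),
...                      list_length_law=("lognormal", 14.0, 0.45), seed=42)
>>> data = fl.generate_dataset(spec)
>>> data.n_respondents, round(data.mean_list_length, 1), len(data.item_universe)
(36, 14.1, 103)
>>> fit = fl.SaturationModel(data).fit_best()
>>> print(fit.summary())
Accumulation fit: NB-log
  observations: 36
  b0 (intercept): 2.0789
  b1 (slope/respondent): -0.0692  (p = 4.72e-08)
  dispersion (NB2 alpha): 0.1156
  loglik: -65.53   AIC: 137.05
  saturation (Y<=1): x = 30.05, N_SAT = 31
  D_SAT = 98.6   D_TOT = 111.6
```

36 interviews with a mean of 14.1 responses each produced 103 distinct
items.  The negative binomial log-link model wins on AIC; new items fall
below one per additional respondent at a sample size of 31, by which point
the model predicts 98.6 items collected out of an extrapolated 111.6 —
close to, and as expected slightly below, the true simulated domain of 120.

```python
>>> est = fl.best_domain_estimate(fl.capture_spectrum(data))
>>> print(est.summary())
Closed-population fit: mh_chao_lb (code 'c')
  observed items S: 103
  estimated unseen f0: 12.7
  estimated domain size: 115.7
  AIC: 92.83   converged: True
  candidates:
     m0           abundance=    103.0 AIC=      inf converged=False
   * mh_chao_lb   abundance=    115.7 AIC=    92.83 converged=True
     mh_poisson2  abundance=    103.6 AIC=   484.75 converged=True
     mh_darroch   abundance=    110.7 AIC=   117.70 converged=True
     mh_gamma     abundance=    271.0 AIC=   164.60 converged=True
```

The homogeneous model cannot fit long-tailed salience at all; the
item-heterogeneity models can, and the selected Chao lower bound estimates
115.7 items.  Salient-item capture shows the probing effect:

```python
>>> sal = fl.salient_set(data)           # prevalence >= 20% in first 20 lists
>>> len(sal), fl.capture_proportion(sal, data, n=10)
(23, 0.9565217391304348)
>>> round(fl.capture_proportion(sal, data, n=10, k=3), 3)
0.391
```

Ten full-listing interviews already capture 96% of the 23 salient items;
ten three-response interviews capture only 39%.

A command-line interface wraps the same pipeline:

```bash
freelists simulate --seed 7 -o lists.csv
freelists analyze lists.csv -o report/
freelists truncate lists.csv -k 3 -o report/
freelists recover --seed 7
```

`analyze` writes per-example salience tables, accumulation series,
capture-recapture candidate tables, saturation and truncation summaries,
and a machine-readable `summary.json`.

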