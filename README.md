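# elevgrad

Tools for dissecting **elevational species-richness gradients** on a bounded
mountain domain — the kind of analysis used to ask why a stream-fish (or any
montane) fauna peaks at mid-elevations: is it climate, geometry, or
evolutionary history?

The package is organised around a banded domain (e.g. 600–4,300 m cut into
nineteen 200-m bands) and provides, for a set of species elevational ranges,
a time-calibrated phylogeny and per-band climate covariates:

* **Richness** — range-interpolated and observed species counts per band
  (`richness`).
* **Mid-domain effect (MDE)** — a random-range-placement null model: each
  empirical range size is kept and its midpoint redrawn uniformly within the
  bounded domain; Monte-Carlo mean and 95% envelope per band, plus an exact
  closed-form expectation used for validation (`mde`).
* **Ancestral elevational ranges** — maximum-likelihood Brownian-motion
  (weighted squared-change parsimony) reconstruction of range midpoints and
  sizes at internal nodes, solved exactly as one linear system (`phylo`).
* **Colonization history** — detects when each lineage's reconstructed
  interval first enters each band (interval endpoints interpolate linearly
  in time along edges; entry times solved in closed form) and summarises
  per-band colonization frequency, oldest age, summed age (SAC) and average
  age (`colonization`).
* **Diversification rates** — method-of-moments net diversification
  estimators: stem `r = ln(n(1−ε)+ε)/t` and the corresponding crown form,
  at relative extinction fractions ε ∈ {0, 0.45, 0.9} (`divrate`).
* **Rapoport's rule** — Stevens' band-mean range size and the cross-species
  (midpoint, range-size) table (`rapoport`).
* **Regression layer** — OLS (degree 1 or 2, optional standardization), VIF
  screening at the <3 convention, and three-set adjusted-R² variance
  partitioning by inclusion–exclusion over the seven submodels (`stats`).
* **Synthetic data** — birth–death trees conditioned on a tip count,
  BM-evolved ranges with known ancestral truth, trend+noise climate tables
  and uniform survey records, all seed-reproducible (`synthetic`).
* **Pipeline** — `analyze()` / `elevgrad run` drive every stage from one
  config and emit a JSON report with CSV mirrors (`pipeline`).

## Worked example

The package ships a deterministic, clearly-labelled *synthetic* stand-in
range table of 19 high-plateau loach-like species (no field data are
redistributed here):

```python
import pandas as pd
import elevgrad as eg

grid = eg.make_grid(600, 4300, 200)          # 19 bands, last = [4200, 4400)
ranges = eg.synthetic_loach_ranges()

srp = eg.interpolate_richness(ranges, grid)
print(srp.counts.tolist())
# [1, 2, 3, 4, 6, 7, 8, 9, 12, 10, 8, 8, 7, 6, 6, 5, 4, 3, 3]

null = eg.simulate_mde(ranges, grid, reps=50_000, seed=1)
fit = eg.ols_regress(srp.counts, pd.DataFrame({"mde": null.mean_richness}))
print(round(fit.r2, 3), round(fit.adj_r2, 3))
# 0.849 0.84
```

Richness is unimodal and peaks at 12 species in the 2,200–2,400 m band.
The null model predicts a symmetric mid-domain hump (mean ≈ 9.8 species in
the central bands); regressing the empirical counts on the null mean shows
the geometric constraint alone explains ~85% of the variance in this
stand-in world.  With a tree and climate table the same workflow continues
through ancestral reconstruction, colonization metrics and variance
partitioning — see `elevgrad run --config run.yaml` or
`elevgrad.analyze(...)`, and `elevgrad simulate` to generate a full
synthetic input set.

## Acceptance script

`scripts/acceptance.py` regenerates the stand-in world from a seed, runs the
complete pipeline (richness, 50,000-rep MDE null model, reconstruction,
colonization, rates, Rapoport profiles, regressions and variance
partitioning) and writes a JSON summary:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The full report (JSON plus CSV mirrors) is written next to the summary
under `results/report/`.
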