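# fertimap

Small-area analysis of fertility inequality for epidemiologists and health
geographers: given census-tract birth counts, woman-year denominators and
five tract-level socioeconomic indicators, the package builds a deprivation
index, computes stratified crude fertility rates, smooths tract rates with
the Besag–York–Mollié (BYM) spatial model, and fits a three-period
ecological regression of fertility on deprivation, reported as relative
risks comparing highly deprived to affluent tracts.

Registry microdata of this kind are rarely shareable, so the package ships a
first-class synthetic-city generator with known ground truth; every stage is
validated against it.

## Models

**Deprivation index.** The five indicators (manual work %, unemployment %,
temporary work %, low education %, low education among 16–29-year-olds %)
are standardized; the index *x* is their first principal component, oriented
so that higher values mean more deprivation, rescaled to mean 0 / sd 1, and
summarized by septiles and the (q5, q95) percentile pair.

**BYM smoothing.** Per tract *i* within one age × nationality × period
stratum:

    O_i ~ Poisson(N_i · exp(α + u_i + v_i))

with `u` an intrinsic CAR (ICAR) spatial field — density ∝
exp(−τ_u/2 · Σ_{i~j}(u_i − u_j)²), sum-to-zero constrained — and
`v_i ~ N(0, 1/τ_v)` unstructured heterogeneity.  Precisions get
Gamma(0.5, 0.0005) hyperpriors.  Smoothed rates are posterior summaries of
1000 · exp(α + u_i + v_i).

**Ecological regression.** Across the three periods jointly, per stratum:

    O_{ip} ~ Poisson(N_{ip} · exp(α_p + (β₁ + δ_p)·x_i + u_{ip} + v_{ip})),  δ₁ = 0

The effect of interest is RR_p = exp((β₁ + δ_p)·(q95 − q5)), the relative
risk comparing the 95th to the 5th percentile of deprivation, with a 95%
equal-tailed credible interval.  Changes of the association between periods
are flagged when the posterior interval of δ₂ (first→second) or δ₃ − δ₂
(second→third) excludes zero.

Inference is by a Metropolis-within-Gibbs sampler (graph-coloured block
updates of the fields, conjugate Gibbs draws of the precisions, plus
precision–field rescaling and slope–field ridge moves that handle the two
classic BYM mixing pathologies); see `docs/methods.md`.

## Worked example

```sh
python analysis/01_simulate_city.py   # 15x15-tract city, true RR = (1.0, 1.5, 2.0)
python analysis/02_deprivation_index.py
python analysis/03_crude_rates.py
python analysis/04_smooth_rates.py
python analysis/05_ecoregression.py
```

The index stage prints

    first principal component explains 99.0% of indicator variance (expect > 75% ...)
    exposure contrast q95 - q5 = 1.552 - (-1.688) = 3.240

i.e. one latent factor dominates the five indicators (the construction
assumes this, and real-city MEDEA indices report > 75%), and the regression
stage recovers the simulated truth, e.g. for all ages 15–49:

    Spanish  15-49  *+ P1: 0.95 [0.84, 1.06]  P2: 1.50 [1.33, 1.69]  P3: 1.97 [1.73, 2.21]

read as: no fertility–deprivation association in the first period (RR ≈ 1),
then RR 1.5 and 2.0 — deprived tracts reaching twice the fertility of
affluent ones — with both period-to-period changes flagged significant
(`*`, `+`), matching the (1.0, 1.5, 2.0) ground truth of the simulation.
The smoothing stage prints the variance removed from crude tract rates
(15–38% here) together with convergence diagnostics.

The same stages are scriptable on real data through the CLI
(`fertimap simulate|index|rates|smooth|regress|run-all`) with counts CSV,
indicators CSV and GAL adjacency inputs.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the full pipeline from scratch on a seeded 10×10 synthetic city —
simulation, index, crude rates, BYM smoothing, stratified regression — and
writes the pipeline outputs (plus a manifest with per-fit convergence
diagnostics) next to the JSON summary.
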