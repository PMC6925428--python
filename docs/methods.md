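# Methods

## The estimation problem

Fertility rates at census-tract level are unstable: the variance of a crude
rate is inversely proportional to its woman-year denominator, and tracts are
drawn to hold only a few hundred women per age group.  Two model-based
devices deal with this.  First, tract rates are smoothed by borrowing
strength from neighbouring tracts (BYM).  Second, the fertility–deprivation
association is estimated at area level (an ecological design): the exposure
is a tract-level deprivation index, the outcome the tract's Poisson birth
count, and the effect a relative risk between extreme percentiles of
deprivation.  Inference is fully Bayesian; the published analyses this
package mirrors used INLA, whereas this implementation uses MCMC — the
contract is the posterior, not the approximation algorithm, and MCMC can be
validated against exact conjugate and brute-force oracles.

## Deprivation index

The five census indicators are standardized to mean 0 / sd 1 (population
sd); the index is the first eigenvector of their correlation matrix applied
to the standardized columns.  Open choices, fixed as follows:

- **Combination rule.** Only "principal components" is stated for the
  original index; we use the first component alone.  The fraction of
  variance it explains (first eigenvalue / 5) is reported so the user can
  verify the single-factor premise (> 0.75 in the real-city analyses).
- **Orientation.** Eigenvectors are sign-ambiguous; the score is oriented to
  correlate positively with the unemployment column, making "higher = more
  deprived" deterministic.
- **Percentiles.** q5/q95 by linear interpolation of order statistics
  (`numpy.percentile`, `method="linear"`); stated for bit-reproducibility.
- **Septiles.** Rank split into 7 groups with sizes differing by at most 1
  (larger groups at the affluent end), stable ties; label 7 = most deprived
  seventh.  Where the source text is ambiguous about the direction of
  "lowest septile", the package only promises label 7 = most deprived and
  leaves legend wording to the user.
- Fewer than 7 tracts: the index is computed (needs ≥ 3) but septile labels
  are `None` rather than a degenerate split.

## Count models

One stratum (age × nationality), one period (smoothing):

    O_i ~ Poisson(N_i e^{α + u_i + v_i}),
    p(u | τ_u) ∝ exp(−τ_u/2 Σ_{i~j}(u_i−u_j)²) · τ_u^{(n−1)/2},   Σ_i u_i = 0,
    v_i ~ N(0, 1/τ_v),   τ_u, τ_v ~ Gamma(0.5, 0.0005),   α flat.

Three periods jointly (regression), with the standardized index x:

    O_{ip} ~ Poisson(N_{ip} e^{α_p + (β₁+δ_p) x_i + u_{ip} + v_{ip}}),   δ₁ = 0,
    β₁, δ₂, δ₃ ~ N(0, 10²),   α_p flat.

Default is an independent (u, v) pair per period; a `shared_fields` switch
fits one shared pair instead.  Which variant the original INLA analyses used
is not recoverable from the published text (the annex is unavailable), so
neither is claimed as "the" published model; period-specific fields are the
conservative default because they let spatial residual structure differ by
period.  Precisions are shared across periods.  The Gamma(0.5, 0.0005)
hyperprior is the long-standing weakly-informative disease-mapping default;
both are config knobs.  The flat prior on α_p is proper a posteriori
whenever the stratum has any births; a Gamma(a₀, b₀) prior on the rate
e^{α_p} is available (log-prior a₀α − b₀e^{α}), which is also what reduces
the model to the exactly-solvable Poisson–Gamma form when both fields are
disabled — the basis of the conjugate test oracle.

Degenerate inputs: cells with N = 0 contribute no likelihood (their
smoothed-rate intervals are prior-driven and flagged); births in a cell with
zero woman-years are an error; disconnected adjacency graphs are rejected
(the ICAR sum-to-zero constraint is only well defined per component).

## Sampler

Metropolis-within-Gibbs, one sweep =

1. `α_p`: scalar adaptive random-walk (RW) per period.
2. `β₁`, then `δ_p`: scalar adaptive RW.
3. Slope–field ridge move, per period: propose β_p → β_p + db with the
   spatial field compensating, u_p → u_p − db·(x − x̄).  Because x is
   centred the linear predictor changes only by the constant db·x̄, so the
   move explores the spatially-confounded direction (smooth exposure vs
   smooth field) at prior cost alone.  Without it, β and τ mixing is
   visibly poor on smooth exposures.
4. `u`: block RW over graph-colour classes (greedy colouring); nodes of one
   colour are conditionally independent given the rest, so a whole class is
   proposed and accepted element-wise.  After the update each field is
   re-centred, its mean transferred to the intercept (likelihood-invariant).
5. `τ_u | u`: conjugate Gibbs, Gamma(a_u + k(n−1)/2, b_u + SS_u/2) with k
   the number of independent fields; then three attempts of a joint rescale
   move (τ_u, u) → (sτ_u, u/√s) — a symmetric RW on log τ_u in the
   (τ_u, u√τ_u) parameterization, where the ICAR factors cancel and only
   the Gamma prior (with Jacobian) and the likelihood of the rescaled field
   remain.  This is the standard remedy for the precision–field ridge that
   makes Gibbs-only τ updates mix slowly.
6. `v`: element-wise adaptive RW; `τ_v | v` Gibbs plus the analogous
   rescale move.

Step sizes adapt toward 44% acceptance during burn-in only (Robbins–Monro
on the log scale, gain min(0.1, 5/(t+10))), so retained draws come from a
fixed-kernel Markov chain.  The cached linear predictor and Poisson means
are updated incrementally and resynchronized every 250 sweeps to stop
floating-point drift.  All chains derive their generators from named
substreams of one seed; identical configuration reproduces identical draws.

Defaults: 2 chains × 5,000 retained, burn-in 2,000, thinning 2 — desk-scale
on a 400-tract lattice (a three-period stratum fit is a few seconds).
Convergence is screened by split-R̂ (each chain halved; R̂ < 1.1 on all
scalar parameters); failure attaches a warning to the draws and marks the
run manifest `unconverged`, never silently.

## Relative risks

Per retained draw, RR_p = exp((β₁+δ_p)(q95−q5)); summaries are the
posterior median (invariant under exp; the mean is also emitted) and the
equal-tailed 95% interval.  "Statistically significant change" between
consecutive periods is operationalized as the 95% equal-tailed interval of
δ₂ (resp. δ₃ − δ₂) excluding zero — the Bayesian analogue of the published
interaction tests, and invariant to reparameterizing periods (testing
δ₃ − δ₂ is identical to testing β₃ − β₂).

## Synthetic city: what it emulates, what it does not

The generator produces a rook-adjacency lattice (contiguity neighbourhoods,
as in census-tract shapefiles), five indicators driven by one spatially
smooth latent factor (ICAR(τ=1) draw plus N(0, 0.5²) tract noise, indicator
noise sd 0.1, baselines on a plausible raw percentage scale), and Poisson
counts from the regression model above.  Chosen once, on field plausibility,
and not revisited:

- baseline rates per 1,000 woman-years: Spanish 8/20/65/22 and LIC
  35/80/80/25 for ages 15–19/20–24/25–34/35–49 — the magnitudes and
  ordering seen in Spanish urban registries, with LIC fertility uniformly
  higher;
- deprivation slope β = 0.2 per index unit in every period unless target
  RRs are requested, in which case per-period slopes are back-computed from
  the realized index span so the truth is exact;
- field precisions τ_u = 10, τ_v = 100 (spatial sd ≈ 0.3 on a lattice,
  unstructured sd 0.1);
- populations log-normal around a median of 500 women per tract-stratum
  (log-sd 0.25), constant over periods.

Deliberately not emulated: real street geography, migration between
periods, within-period yearly resolution, dual-nationality ambiguity.  A
green recovery test therefore establishes that the estimator recovers known
truth *under the model's own data-generating process with spatially
confounded exposure* — not that the published city estimates are correct.
Because the latent deprivation factor is itself spatially smooth, the
simulations do exercise the exposure–field confounding that is the hard
part of this design.

The 15–49 aggregate rows are sums of the four narrow age groups; their
fitted log-rate is not exactly linear in x (a sum of Poissons with
different baselines), but with a shared slope the approximation error is
absorbed by the fields.

## Stratification conventions

Nationality: Spanish nationals and nationals of countries at or above the
World Bank high-income threshold (GNI per capita ≥ $12,056) form the
"Spanish" group; all others "LIC".  Age groups 15–19, 20–24, 25–34, 35–49
by completed years at delivery (one convention had to be fixed), plus the
15–49 total; ages outside 15–49 are errors, not silent drops.  Periods
P1 = 1999–2003, P2 = 2004–2008, P3 = 2009–2013; denominators are woman-years
summed over all years of the period (the source tables' note about "4
years" conflicts with the five-calendar-year period labels; the year lists
are exposed in config rather than guessing the published choice).

## Known limitations

- Ecological design: tract-level associations do not license individual-
  level conclusions.
- The ICAR constraint (and hence the package) requires a connected
  adjacency graph; islands must be bridged or dropped upstream.
- Credible-interval coverage is verified at the synthetic world's sample
  sizes; very sparse strata (zero births) are reported with a sparsity flag
  and prior-dominated intervals rather than refused.
- The septile labelling and percentile conventions are package choices;
  comparisons with other MEDEA implementations should check them.
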