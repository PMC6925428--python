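"""Ecological regression of fertility on deprivation across three periods.

The association of interest is between the tract deprivation index ``x`` and
the fertility rate, per period, within one age/nationality stratum:

    O_{i,p} ~ Poisson(N_{i,p} * exp(alpha_p + (beta1 + delta_p) * x_i
                                     + u_{i,p} + v_{i,p}))

with ``delta_1 = 0`` so the period slopes are ``beta_p = beta1 + delta_p``.
The reported effect is the relative risk comparing the 95th to the 5th
percentile of deprivation, ``RR_p = exp(beta_p * (q95 - q5))``, with a 95%
equal-tailed credible interval; change between consecutive periods is flagged
when the posterior interval of ``delta_2`` (first-to-second) or
``delta_3 - delta_2`` (second-to-third) excludes zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .deprivation import DeprivationIndex
from .graph import AdjacencyGraph
from .mcmc import MCMCConfig, PosteriorDraws, sample_poisson_bym
from .rates import AGE_ALL, AGE_GROUPS, NATIONALITIES, PERIODS, validate_counts

__all__ = ["RRResult", "fit_ecoregression", "relative_risk", "run_stratified_analysis"]


@dataclass(frozen=True)
class RRResult:
    """Per-period relative risks (95th vs 5th deprivation percentile).

    ``sig_12`` / ``sig_23`` flag a statistically significant change of the
    association between consecutive periods (95% credible interval of the
    corresponding interaction contrast excluding zero).
    """

    periods: tuple[str, ...]
    rr: np.ndarray       # posterior median per period
    rr_mean: np.ndarray
    lo95: np.ndarray
    hi95: np.ndarray
    sig_12: bool
    sig_23: bool

    def __post_init__(self):
        if np.any(self.rr <= 0):
            raise AssertionError("relative risks must be positive")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "period": list(self.periods),
                "rr": self.rr,
                "rr_mean": self.rr_mean,
                "lo95": self.lo95,
                "hi95": self.hi95,
                "sig_12": self.sig_12,
                "sig_23": self.sig_23,
            }
        )


def _stratum_matrices(
    counts: pd.DataFrame,
    tract_id: tuple[str, ...],
    periods: tuple[str, ...],
) -> tuple[np.ndarray, np.ndarray]:
    """Pivot one stratum's long counts into (n, P) O and N matrices."""
    counts = validate_counts(counts)
    have = set(counts["period"])
    missing = [p for p in periods if p not in have]
    if missing:
        raise ValueError(f"counts are missing periods {missing}")
    O = np.zeros((len(tract_id), len(periods)))
    N = np.zeros_like(O)
    pos = {t: i for i, t in enumerate(tract_id)}
    ppos = {p: j for j, p in enumerate(periods)}
    ti = counts["tract_id"].astype(str).map(pos)
    if ti.isna().any():
        bad = counts.loc[ti.isna(), "tract_id"].iloc[0]
        raise ValueError(f"counts reference tract {bad!r} not in the index/tract set")
    pj = counts["period"].map(ppos)
    np.add.at(O, (ti.to_numpy(int), pj.to_numpy(int)), counts["births"].to_numpy(float))
    np.add.at(N, (ti.to_numpy(int), pj.to_numpy(int)), counts["women"].to_numpy(float))
    return O, N


def fit_ecoregression(
    counts: pd.DataFrame,
    index: DeprivationIndex,
    graph: AdjacencyGraph,
    mcmc: MCMCConfig,
    *,
    periods: tuple[str, ...] = PERIODS,
    shared_fields: bool = False,
    beta_prior_sd: float = 10.0,
    tau_u_prior: tuple[float, float] = (0.5, 0.0005),
    tau_v_prior: tuple[float, float] = (0.5, 0.0005),
    store_fields: bool = False,
) -> PosteriorDraws:
    """Fit the three-period deprivation regression for one stratum.

    ``counts`` holds one age/nationality stratum in the long counts schema;
    rows are aligned to ``index.tract_id`` order.  Flat priors on the period
    intercepts, Normal(0, ``beta_prior_sd``^2) on ``beta1`` and the
    interaction offsets; period-specific BYM fields by default
    (``shared_fields=True`` shares one pair of fields across periods).
    """
    if len(periods) < 2:
        raise ValueError("the period-interaction model needs at least two periods")
    O, N = _stratum_matrices(counts, index.tract_id, periods)
    for j, p in enumerate(periods):
        if not np.any(N[:, j] > 0):
            raise ValueError(f"period {p} has no woman-years in this stratum")
    return sample_poisson_bym(
        O,
        N,
        graph,
        mcmc,
        x=index.x,
        periods=periods,
        shared_fields=shared_fields,
        beta_prior_sd=beta_prior_sd,
        tau_u_prior=tau_u_prior,
        tau_v_prior=tau_v_prior,
        store_fields=store_fields,
    )


def relative_risk(draws: PosteriorDraws, span: tuple[float, float]) -> RRResult:
    """Summarize the posterior of ``RR_p = exp(beta_p * (q95 - q5))``.

    ``span`` is the (q5, q95) pair from the deprivation index.  The median is
    used as the point summary (invariant under the exp transform); the mean
    is also reported.  Change flags test ``delta_2`` and ``delta_3 - delta_2``
    against zero at the 95% level.
    """
    q5, q95 = span
    if not q95 > q5:
        raise ValueError("need q95 > q5 for a positive exposure contrast")
    if "beta1" not in draws.params:
        raise ValueError("draws come from a model without a deprivation slope")
    width = q95 - q5
    beta1 = draws.stacked("beta1")  # (draws,)
    delta = draws.stacked("delta")  # (draws, P)
    beta_p = beta1[:, None] + delta
    rr_draws = np.exp(beta_p * width)
    lo, med, hi = np.percentile(rr_draws, [2.5, 50.0, 97.5], axis=0)

    def _excludes_zero(samples: np.ndarray) -> bool:
        a, b = np.percentile(samples, [2.5, 97.5])
        return bool(a > 0 or b < 0)

    P = delta.shape[1]
    sig_12 = _excludes_zero(delta[:, 1]) if P >= 2 else False
    sig_23 = _excludes_zero(delta[:, 2] - delta[:, 1]) if P >= 3 else False
    return RRResult(
        periods=draws.periods,
        rr=med,
        rr_mean=rr_draws.mean(axis=0),
        lo95=lo,
        hi95=hi,
        sig_12=sig_12,
        sig_23=sig_23,
    )


def run_stratified_analysis(
    counts: pd.DataFrame,
    index: DeprivationIndex,
    graph: AdjacencyGraph,
    mcmc: MCMCConfig,
    *,
    age_groups: tuple[str, ...] = AGE_GROUPS + (AGE_ALL,),
    nationalities: tuple[str, ...] = NATIONALITIES,
    periods: tuple[str, ...] = PERIODS,
    shared_fields: bool = False,
) -> pd.DataFrame:
    """Independent regression fits for every age x nationality stratum.

    Returns a long table shaped like the per-city forest-plot panels: one row
    per (nationality, age_group, period) with the RR, its 95% interval, the
    two period-change flags, a data-sparsity flag (no births anywhere in the
    stratum) and the maximum split-R-hat of the fit.  Each stratum uses a
    named seed substream of ``mcmc.seed`` so single strata can be re-run in
    isolation.
    """
    from ._rng import child_seed
    from .mcmc import gelman_rubin

    counts = validate_counts(counts)
    rows = []
    for nat in nationalities:
        for age in age_groups:
            sub = counts[(counts["age_group"] == age) & (counts["nationality"] == nat)]
            if sub.empty:
                raise ValueError(f"no counts for stratum age={age}, nationality={nat}")
            stratum_seed = int(np.random.SeedSequence(
                child_seed(mcmc.seed, "stratum", f"{age}|{nat}")
            ).generate_state(1, dtype=np.uint32)[0] % (2**31))
            cfg = MCMCConfig(
                seed=stratum_seed,
                n_chains=mcmc.n_chains,
                n_iter=mcmc.n_iter,
                burn_in=mcmc.burn_in,
                thin=mcmc.thin,
            )
            try:
                draws = fit_ecoregression(
                    sub, index, graph, cfg, periods=periods, shared_fields=shared_fields
                )
            except ValueError as exc:
                raise ValueError(f"stratum age={age}, nationality={nat}: {exc}") from exc
            rr = relative_risk(draws, (index.q5, index.q95))
            sparse = int(sub["births"].sum()) == 0
            max_rhat = max(gelman_rubin(draws).values()) if mcmc.n_chains >= 2 else np.nan
            for j, p in enumerate(periods):
                rows.append(
                    {
                        "nationality": nat,
                        "age_group": age,
                        "period": p,
                        "rr": rr.rr[j],
                        "rr_mean": rr.rr_mean[j],
                        "lo95": rr.lo95[j],
                        "hi95": rr.hi95[j],
                        "sig_12": rr.sig_12,
                        "sig_23": rr.sig_23,
                        "sparse": sparse,
                        "max_rhat": max_rhat,
                    }
                )
    return pd.DataFrame(rows)
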