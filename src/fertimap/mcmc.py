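"""Metropolis-within-Gibbs sampler for Poisson count models with BYM fields.

One engine serves both the single-stratum smoothing model and the
three-period ecological regression:

    O_{i,p} ~ Poisson(N_{i,p} * exp(eta_{i,p}))
    eta_{i,p} = alpha_p + (beta1 + delta_p) * x_i + u_{i,p} + v_{i,p}

with ``u`` an intrinsic CAR (ICAR) spatial field, ``v`` iid Normal(0, 1/tau_v)
heterogeneity, Gamma hyperpriors on both precisions, an (optionally
informative Gamma-on-the-rate) prior on each ``alpha_p`` and Normal(0, sd^2)
priors on the regression coefficients.  The covariate block is switched off
for plain smoothing; either field can be disabled, which reduces the model to
its conjugate Poisson-Gamma limit used as a test oracle.

Updates per sweep: adaptive random-walk Metropolis for ``alpha_p``, ``beta1``
and ``delta_p``; block random-walk updates of ``u`` over graph-colour classes
(nodes of one colour are conditionally independent under the ICAR prior, so a
whole class is proposed and accepted element-wise); element-wise updates of
``v``; conjugate Gibbs draws of ``tau_u | u ~ Gamma(a_u + k(n-1)/2,
b_u + SS_u/2)`` (``k`` = number of independent fields, ``SS_u`` the sum of
squared neighbour differences) and ``tau_v | v``.  The spatial field is
re-centred to sum to zero after every sweep, transferring its mean to the
intercept so the likelihood is untouched.  Step sizes adapt toward 44%
acceptance during burn-in only, keeping the retained chain Markovian.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._rng import child_seed
from .graph import AdjacencyGraph

__all__ = [
    "MCMCConfig",
    "PosteriorDraws",
    "ConvergenceWarning",
    "icar_log_kernel",
    "sample_poisson_bym",
    "gelman_rubin",
]

_TARGET_ACCEPT = 0.44  # optimal-ish for one-dimensional random-walk proposals
_RESYNC_EVERY = 250  # sweeps between full recomputations of cached exp(eta)


class ConvergenceWarning(UserWarning):
    """Chains failed the split-R-hat < 1.1 screen; results may be unreliable."""


@dataclass(frozen=True)
class MCMCConfig:
    """Chain settings.  ``n_iter`` is the number of retained draws per chain."""

    seed: int
    n_chains: int = 2
    n_iter: int = 5000
    burn_in: int = 2000
    thin: int = 2

    def __post_init__(self):
        if self.n_chains < 1:
            raise ValueError("need at least one chain")
        if self.n_iter < 1 or self.burn_in < 0 or self.thin < 1:
            raise ValueError("n_iter >= 1, burn_in >= 0, thin >= 1 required")


@dataclass
class PosteriorDraws:
    """Retained MCMC samples plus chain metadata.

    ``params`` maps parameter names to arrays of shape
    ``(n_chains, n_draws, ...)``: ``alpha`` and ``delta`` carry a trailing
    period axis, ``u``/``v`` trailing ``(n_tracts, n_fields)`` axes,
    ``beta1``/``tau_u``/``tau_v`` are scalar per draw.
    """

    params: dict[str, np.ndarray]
    periods: tuple[str, ...]
    config: MCMCConfig
    warnings: list[str] = field(default_factory=list)

    @property
    def n_chains(self) -> int:
        return next(iter(self.params.values())).shape[0]

    @property
    def n_draws(self) -> int:
        return next(iter(self.params.values())).shape[1]

    def stacked(self, name: str) -> np.ndarray:
        """All chains concatenated: shape ``(n_chains * n_draws, ...)``."""
        a = self.params[name]
        return a.reshape(-1, *a.shape[2:])

    def to_long_frame(self, include_fields: bool = False):
        """Long-format draws table: chain, iter, parameter, value.

        Scalar parameters only by default; ``include_fields`` adds every
        field component (``u[i,p]``, ``v[i,p]``), which can be large.
        """
        import pandas as pd

        series = dict(self.scalar_series())
        if include_fields:
            for name in ("u", "v"):
                if name in self.params:
                    a = self.params[name]  # (C, S, n, K)
                    for i in range(a.shape[2]):
                        for k in range(a.shape[3]):
                            series[f"{name}[{i},{k}]"] = a[:, :, i, k]
        frames = []
        for pname, a in series.items():
            c, s = a.shape
            frames.append(
                pd.DataFrame(
                    {
                        "chain": np.repeat(np.arange(c), s),
                        "iter": np.tile(np.arange(s), c),
                        "parameter": pname,
                        "value": a.ravel(),
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    def scalar_series(self) -> dict[str, np.ndarray]:
        """Scalar views ``name -> (n_chains, n_draws)`` for diagnostics."""
        out: dict[str, np.ndarray] = {}
        for name, a in self.params.items():
            if a.ndim == 2:
                out[name] = a
            elif a.ndim == 3 and name in ("alpha", "delta"):
                for p, label in enumerate(self.periods):
                    out[f"{name}[{label}]"] = a[:, :, p]
        return out


def icar_log_kernel(u: np.ndarray, graph: AdjacencyGraph, tau_u: float) -> float:
    """Log-density of the ICAR prior up to an additive constant.

    ``-(tau/2) * sum_{i~j} (u_i - u_j)^2 + ((n-1)/2) * log(tau)``, the sum
    running over unordered neighbour pairs; rank n-1 is the intrinsic-prior
    convention and is what makes the Gibbs update for ``tau_u`` correct.
    """
    u = np.asarray(u, dtype=float)
    if u.shape != (graph.n,):
        raise ValueError(f"u has length {u.shape}, graph has {graph.n} tracts")
    if tau_u <= 0:
        raise ValueError("tau_u must be positive")
    if not np.all(np.isfinite(u)):
        raise ValueError("u must be finite")
    e = graph.edges
    ss = float(np.sum((u[e[:, 0]] - u[e[:, 1]]) ** 2)) if len(e) else 0.0
    return -0.5 * tau_u * ss + 0.5 * (graph.n - 1) * np.log(tau_u)


def _validate_counts_arrays(O: np.ndarray, N: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    O = np.asarray(O, dtype=float)
    N = np.asarray(N, dtype=float)
    if O.ndim == 1:
        O = O[:, None]
    if N.ndim == 1:
        N = N[:, None]
    if O.shape != N.shape:
        raise ValueError("O and N shapes differ")
    if np.any(N < 0) or np.any(O < 0):
        raise ValueError("counts must be non-negative")
    if np.any((N == 0) & (O > 0)):
        raise ValueError("births observed in a cell with zero woman-years")
    if not N.sum() > 0:
        raise ValueError("all denominators are zero; nothing to fit")
    return O, N


def sample_poisson_bym(
    O: np.ndarray,
    N: np.ndarray,
    graph: AdjacencyGraph,
    config: MCMCConfig,
    *,
    x: np.ndarray | None = None,
    periods: Sequence[str] = ("P1",),
    spatial: bool = True,
    heterogeneous: bool = True,
    shared_fields: bool = False,
    alpha_prior: tuple[float, float] = (0.0, 0.0),
    tau_u_prior: tuple[float, float] = (0.5, 0.0005),
    tau_v_prior: tuple[float, float] = (0.5, 0.0005),
    beta_prior_sd: float = 10.0,
    store_fields: bool = True,
) -> PosteriorDraws:
    """Run the sampler and return retained draws.

    Parameters
    ----------
    O, N
        Birth counts and woman-years, shape ``(n_tracts, n_periods)`` (a
        single period may be passed as ``(n_tracts,)``).
    x
        Standardized per-tract covariate; ``None`` disables the regression
        block (plain BYM smoothing).
    alpha_prior
        ``(a0, b0)`` of a Gamma prior on the rate ``exp(alpha_p)``;
        ``(0, 0)`` is the flat improper prior on ``alpha_p`` itself.
    shared_fields
        If True one spatial/heterogeneous field is shared by all periods;
        default is an independent pair of fields per period.
    """
    O, N = _validate_counts_arrays(O, N)
    n, P = O.shape
    if graph.n != n:
        raise ValueError(f"graph has {graph.n} tracts, counts have {n}")
    if len(periods) != P:
        raise ValueError("period labels do not match the count matrix")
    covariate = x is not None
    if covariate:
        x = np.asarray(x, dtype=float)
        if x.shape != (n,):
            raise ValueError("covariate must have one value per tract")
        if np.ptp(x) == 0:
            raise ValueError("covariate is constant; the slope is not identifiable")
    if spatial:
        graph.require_connected()

    K = 1 if shared_fields else P  # number of independent field columns
    colors = graph.coloring() if spatial else []
    W = graph.adjacency_matrix() if spatial else None
    deg = graph.degrees().astype(float)
    e0, e1 = (graph.edges[:, 0], graph.edges[:, 1]) if spatial else (None, None)
    a0, b0 = alpha_prior
    au, bu = tau_u_prior
    av, bv = tau_v_prior

    Osum = O.sum(axis=0)  # per period
    Orow = O.sum(axis=1)  # per tract
    if covariate:
        OX = (O * x[:, None]).sum(axis=0)
        OXtot = OX.sum()
        xbar = x.mean()
        xc = x - xbar  # exactly centred copy used by the ridge move
        if spatial:
            xLx = float(xc @ graph.laplacian() @ xc)

    n_store = config.n_iter
    n_sweeps = config.burn_in + config.n_iter * config.thin
    store: dict[str, np.ndarray] = {
        "alpha": np.empty((config.n_chains, n_store, P)),
        "tau_u": np.empty((config.n_chains, n_store)),
        "tau_v": np.empty((config.n_chains, n_store)),
    }
    if covariate:
        store["beta1"] = np.empty((config.n_chains, n_store))
        store["delta"] = np.empty((config.n_chains, n_store, P))
    if store_fields and spatial:
        store["u"] = np.empty((config.n_chains, n_store, n, K))
    if store_fields and heterogeneous:
        store["v"] = np.empty((config.n_chains, n_store, n, P))

    for chain in range(config.n_chains):
        rng = np.random.Generator(
            np.random.PCG64(np.random.SeedSequence(child_seed(config.seed, "chain", chain)))
        )
        # --- state ---
        with np.errstate(divide="ignore"):
            alpha = np.log((Osum + 0.5) / np.maximum(N.sum(axis=0), 1.0))
        beta1 = 0.0
        delta = np.zeros(P)
        U = np.zeros((n, K))
        V = np.zeros((n, P))
        tau_u, tau_v = 10.0, 10.0

        def eta_now():
            Ub = U if K == P else np.repeat(U, P, axis=1)
            eta = alpha[None, :] + Ub + V
            if covariate:
                eta = eta + np.outer(x, beta1 + delta)
            return eta

        ETA = eta_now()
        M = N * np.exp(ETA)

        # adaptive step sizes (log scale), frozen after burn-in
        s_alpha = np.full(P, 0.1)
        s_beta = 0.1
        s_delta = np.full(P, 0.1)
        s_u = 0.5
        s_v = 0.5
        s_su = 0.5  # log-scale steps of the precision-field rescale moves
        s_sv = 0.5
        s_r = np.full(P, 0.1)  # slope-field ridge move steps

        stored = 0
        for t in range(n_sweeps):
            adapting = t < config.burn_in
            gamma = min(0.1, 5.0 / (t + 10.0)) if adapting else 0.0

            # alpha_p: independent scalar RW per period
            da = s_alpha * rng.standard_normal(P)
            Msum = M.sum(axis=0)
            dlp = da * Osum - np.expm1(da) * Msum
            if a0 > 0 or b0 > 0:
                dlp += a0 * da - b0 * (np.exp(alpha + da) - np.exp(alpha))
            acc = np.log(rng.random(P)) < dlp
            if np.any(acc):
                alpha[acc] += da[acc]
                ETA[:, acc] += da[acc]
                M[:, acc] *= np.exp(da[acc])
            if adapting:
                s_alpha *= np.exp(gamma * (np.exp(np.minimum(dlp, 0.0)) - _TARGET_ACCEPT))

            if covariate:
                # beta1: shared slope across all periods
                db = s_beta * rng.standard_normal()
                g = np.expm1(db * x)
                dlp_b = db * OXtot - g @ M.sum(axis=1)
                dlp_b += (beta1**2 - (beta1 + db) ** 2) / (2 * beta_prior_sd**2)
                if np.log(rng.random()) < dlp_b:
                    beta1 += db
                    ETA += db * x[:, None]
                    M *= np.exp(db * x)[:, None]
                if adapting:
                    s_beta *= np.exp(gamma * (np.exp(min(dlp_b, 0.0)) - _TARGET_ACCEPT))

                # delta_p, p >= 2 (delta_1 pinned at 0)
                for p in range(1, P):
                    dd = s_delta[p] * rng.standard_normal()
                    g = np.expm1(dd * x)
                    dlp_d = dd * OX[p] - g @ M[:, p]
                    dlp_d += (delta[p] ** 2 - (delta[p] + dd) ** 2) / (2 * beta_prior_sd**2)
                    if np.log(rng.random()) < dlp_d:
                        delta[p] += dd
                        ETA[:, p] += dd * x
                        M[:, p] *= np.exp(dd * x)
                    if adapting:
                        s_delta[p] *= np.exp(gamma * (np.exp(min(dlp_d, 0.0)) - _TARGET_ACCEPT))

                if spatial and K == P:
                    # slope-field ridge move: beta_p -> beta_p + db with the
                    # spatial field compensating (u_p -> u_p - db * xc).  With
                    # x centred the linear predictor only shifts by the
                    # constant db * mean(x), so the move walks the spatially
                    # confounded direction at prior cost alone — this is what
                    # lets the slope and the ICAR field decorrelate.
                    Lu = deg[:, None] * U - W @ U
                    Lxc = deg * xc - W @ xc
                    for p in range(P):
                        db = s_r[p] * rng.standard_normal()
                        c = db * xbar
                        dlp_r = c * Osum[p] - np.expm1(c) * M[:, p].sum()
                        dlp_r += -0.5 * tau_u * (db * db * xLx - 2.0 * db * (xc @ Lu[:, p]))
                        if p == 0:
                            dlp_r += (beta1**2 - (beta1 + db) ** 2) / (2 * beta_prior_sd**2)
                            dlp_r += np.sum(
                                delta[1:] ** 2 - (delta[1:] - db) ** 2
                            ) / (2 * beta_prior_sd**2)
                        else:
                            dlp_r += (delta[p] ** 2 - (delta[p] + db) ** 2) / (2 * beta_prior_sd**2)
                        if np.log(rng.random()) < dlp_r:
                            U[:, p] -= db * xc
                            Lu[:, p] -= db * Lxc
                            if p == 0:
                                beta1 += db
                                delta[1:] -= db
                            else:
                                delta[p] += db
                            ETA[:, p] += c
                            M[:, p] *= np.exp(c)
                        if adapting:
                            s_r[p] *= np.exp(gamma * (np.exp(min(dlp_r, 0.0)) - _TARGET_ACCEPT))

            if spatial:
                # u: block RW over colour classes, element-wise acceptance
                for c in colors:
                    S = W @ U  # (n, K); rebuilt per class because U changed
                    dU = s_u * rng.standard_normal((len(c), K))
                    if K == P:
                        dll = O[c] * dU - M[c] * np.expm1(dU)
                    else:  # one shared field: likelihood sums over periods
                        dll = Orow[c][:, None] * dU - M[c].sum(axis=1, keepdims=True) * np.expm1(dU)
                    dpr = -0.5 * tau_u * (
                        deg[c][:, None] * ((U[c] + dU) ** 2 - U[c] ** 2) - 2.0 * dU * S[c]
                    )
                    dlp_u = dll + dpr
                    acc = np.log(rng.random((len(c), K))) < dlp_u
                    dap = np.where(acc, dU, 0.0)
                    U[c] += dap
                    if K == P:
                        ETA[c] += dap
                        M[c] *= np.exp(dap)
                    else:
                        ETA[c] += dap  # broadcasts (|c|,1) over periods
                        M[c] *= np.exp(dap)
                    if adapting:
                        rate = float(np.exp(np.minimum(dlp_u, 0.0)).mean())
                        s_u *= np.exp(gamma * (rate - _TARGET_ACCEPT))

                # re-centre each field, moving its mean into the intercept(s)
                m = U.mean(axis=0)
                U -= m
                alpha += m if K == P else m[0]

                # tau_u | u : conjugate Gamma
                ss_u = float(np.sum((U[e0] - U[e1]) ** 2))
                tau_u = rng.gamma(au + K * (n - 1) / 2.0, 1.0 / (bu + ss_u / 2.0))

                # joint rescale (tau_u, u) -> (s*tau_u, u/sqrt(s)): moves along
                # the precision-field ridge that makes tau_u mix slowly under
                # Gibbs alone.  In the (tau_u, u*sqrt(tau_u)) parameterization
                # this is a symmetric RW on log tau_u; the ICAR factors cancel,
                # leaving the Gamma prior (with log-scale Jacobian) and the
                # likelihood change from the rescaled field.
                for _ in range(3):  # repeated attempts: the ridge is narrow
                    eps = s_su * rng.standard_normal()
                    s = np.exp(eps)
                    dU_all = U * (1.0 / np.sqrt(s) - 1.0)
                    if K == P:
                        dlp_s = float(np.sum(O * dU_all) - np.sum(M * np.expm1(dU_all)))
                    else:
                        dlp_s = float(
                            np.sum(Orow[:, None] * dU_all)
                            - np.sum(M.sum(axis=1, keepdims=True) * np.expm1(dU_all))
                        )
                    dlp_s += au * eps - bu * tau_u * (s - 1.0)
                    if np.log(rng.random()) < dlp_s:
                        tau_u *= s
                        U += dU_all
                        ETA += dU_all  # broadcasts (n,1) over periods when shared
                        M *= np.exp(dU_all)
                    if adapting:
                        s_su *= np.exp(gamma * (np.exp(min(dlp_s, 0.0)) - _TARGET_ACCEPT))

            if heterogeneous:
                dV = s_v * rng.standard_normal((n, P))
                dlp_v = O * dV - M * np.expm1(dV) - 0.5 * tau_v * (2 * V * dV + dV**2)
                acc = np.log(rng.random((n, P))) < dlp_v
                dap = np.where(acc, dV, 0.0)
                V += dap
                ETA += dap
                M *= np.exp(dap)
                if adapting:
                    rate = float(np.exp(np.minimum(dlp_v, 0.0)).mean())
                    s_v *= np.exp(gamma * (rate - _TARGET_ACCEPT))

                tau_v = rng.gamma(av + n * P / 2.0, 1.0 / (bv + float(np.sum(V**2)) / 2.0))

                # joint rescale (tau_v, v), same ridge move as for the spatial
                # field; the iid Normal factors cancel in the transformed space
                for _ in range(3):
                    eps = s_sv * rng.standard_normal()
                    s = np.exp(eps)
                    dV_all = V * (1.0 / np.sqrt(s) - 1.0)
                    dlp_s = float(np.sum(O * dV_all) - np.sum(M * np.expm1(dV_all)))
                    dlp_s += av * eps - bv * tau_v * (s - 1.0)
                    if np.log(rng.random()) < dlp_s:
                        tau_v *= s
                        V += dV_all
                        ETA += dV_all
                        M *= np.exp(dV_all)
                    if adapting:
                        s_sv *= np.exp(gamma * (np.exp(min(dlp_s, 0.0)) - _TARGET_ACCEPT))

            # periodically resynchronise the multiplicative caches
            if (t + 1) % _RESYNC_EVERY == 0:
                ETA = eta_now()
                M = N * np.exp(ETA)

            if t >= config.burn_in and (t - config.burn_in) % config.thin == 0:
                store["alpha"][chain, stored] = alpha
                store["tau_u"][chain, stored] = tau_u
                store["tau_v"][chain, stored] = tau_v
                if covariate:
                    store["beta1"][chain, stored] = beta1
                    store["delta"][chain, stored] = delta
                if "u" in store:
                    store["u"][chain, stored] = U
                if "v" in store:
                    store["v"][chain, stored] = V
                stored += 1
        assert stored == n_store

    draws = PosteriorDraws(params=store, periods=tuple(periods), config=config)
    if config.n_chains >= 2:
        rhats = gelman_rubin(draws)
        bad = {k: v for k, v in rhats.items() if v > 1.1}
        if bad:
            msg = "MCMC did not converge (split R-hat > 1.1): " + ", ".join(
                f"{k}={v:.3f}" for k, v in sorted(bad.items())
            )
            draws.warnings.append(msg)
            warnings.warn(msg, ConvergenceWarning)
    return draws


def gelman_rubin(draws: PosteriorDraws | dict[str, np.ndarray]) -> dict[str, float]:
    """Split-R-hat per scalar parameter.

    Each chain is split in half, giving ``2 * n_chains`` sequences; R-hat is
    ``sqrt(((m-1)/m * W + B/m) / W)`` with ``W`` the mean within-sequence
    variance, ``B/m`` the between-sequence contribution and ``m`` the split
    length.  Constant chains are reported as exactly 1.  Values are >= 1 up
    to floating-point noise; < 1.1 on the model's scalar parameters is the
    convergence screen used throughout.
    """
    series = draws.scalar_series() if isinstance(draws, PosteriorDraws) else draws
    out: dict[str, float] = {}
    for name, a in series.items():
        a = np.asarray(a, dtype=float)
        if a.ndim != 2:
            raise ValueError(f"{name}: expected (n_chains, n_draws)")
        c, s = a.shape
        if c < 2:
            raise ValueError("R-hat needs at least 2 chains")
        if s < 10:
            raise ValueError("R-hat needs at least 10 retained draws per chain")
        half = s // 2
        seqs = np.concatenate([a[:, :half], a[:, half : 2 * half]], axis=0)  # (2c, half)
        if np.ptp(seqs) == 0:
            out[name] = 1.0
            continue
        m = half
        within = seqs.var(axis=1, ddof=1)
        W = within.mean()
        B = m * seqs.mean(axis=1).var(ddof=1)
        if W == 0:
            out[name] = np.inf
            continue
        var_hat = (m - 1) / m * W + B / m
        out[name] = float(np.sqrt(var_hat / W))
    return out
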