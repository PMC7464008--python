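"""Hierarchical Bayesian estimation of EWA parameters.

Model
-----
Each participant i has an unconstrained parameter vector
``theta_i = (theta_alpha, theta_rho, theta_beta)`` with

* person level:  ``theta_ip ~ Normal(mu_p, sigma_p)``
* population:    ``mu_p ~ Normal(0, 10)``, ``sigma_p ~ half-Cauchy(0, 5)``
* likelihood:    the EWA session log-likelihood evaluated at the
  constrained parameters ``alpha = Phi(theta_alpha)``,
  ``rho = Phi(theta_rho)``, ``beta = 10 * Phi(theta_beta)``
  (Phi the standard normal CDF).

Sampler
-------
A blocked adaptive Metropolis-within-Gibbs scheme that exploits the
model's conditional-independence structure:

* per-participant joint random-walk Metropolis updates of ``theta_i`` on
  the unconstrained scale, vectorised across participants and chains,
  with proposal scales adapted during warm-up toward a target acceptance
  rate;
* exact conjugate Gibbs draws for each population mean ``mu_p``;
* univariate slice sampling for each population scale ``sigma_p`` (on the
  log scale, Jacobian included);
* per-parameter joint *translation* moves (shift ``mu_p`` and every
  ``theta_ip`` together) and *rescale* moves (scale ``sigma_p`` and every
  deviation ``theta_ip - mu_p`` together, with the ``c**n`` Jacobian),
  which keep the population location and scale mobile even when the
  likelihood is nearly flat in a parameter.

Four independent chains are run by default; convergence is summarised by
the split-chain potential-scale-reduction statistic (R-hat) and a run is
flagged (not rejected) when any monitored R-hat exceeds 1.1.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr

from .cohort import BETA_SCALE
from .ewa import EWAParams, SessionData, loglik_trials_batch, sessions_to_arrays

__all__ = [
    "HyperParams",
    "SamplerConfig",
    "PosteriorResult",
    "fit_hierarchical",
    "map_estimates",
    "compute_waic",
    "rhat",
]

_PARAM_NAMES = ("alpha", "rho", "beta")

# Priors: mu ~ Normal(0, MU_PRIOR_SD), sigma ~ half-Cauchy(0, SIGMA_PRIOR_SCALE).
MU_PRIOR_SD = 10.0
SIGMA_PRIOR_SCALE = 5.0


@dataclass(frozen=True)
class HyperParams:
    """Population-level mean and scale on the unconstrained scale."""

    mu: tuple[float, float, float]
    sigma: tuple[float, float, float]

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.sigma):
            raise ValueError("population sigma must be positive")


@dataclass(frozen=True)
class SamplerConfig:
    """MCMC configuration: 4 chains x 1000 kept iterations by default."""

    chains: int = 4
    draws: int = 1000
    warmup: int = 1000
    thin: int = 1
    mh_sweeps: int = 3
    target_accept: float = 0.35
    seed: int = 0
    max_pointwise_draws: int = 1000

    def __post_init__(self) -> None:
        if self.chains < 1 or self.draws < 1 or self.warmup < 0 or self.thin < 1:
            raise ValueError("invalid sampler configuration")


@dataclass
class PosteriorResult:
    """Posterior draws, diagnostics and derived summaries.

    ``theta`` has shape (chains, draws, n, 3) on the unconstrained scale;
    ``log_density`` stores the joint model log-density of each draw (used
    for the MAP point estimate). ``pointwise_loglik`` is a
    (subsampled draws, participants x trials) matrix backing the WAIC, and
    ``pointwise_params`` the constrained parameter values of those draws.
    """

    theta: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray
    log_density: np.ndarray
    participant_ids: list[str]
    config: SamplerConfig
    rhat: dict[str, float]
    converged: bool
    accept_rate: float
    waic: float = math.nan
    pointwise_loglik: np.ndarray | None = None
    pointwise_params: np.ndarray | None = None
    map_estimates: list[EWAParams] = field(default_factory=list)

    @property
    def map_table(self):
        """MAP estimates as a DataFrame (participant_id, alpha_map, ...)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "participant_id": self.participant_ids,
                "alpha_map": [p.alpha for p in self.map_estimates],
                "rho_map": [p.rho for p in self.map_estimates],
                "beta_map": [p.beta for p in self.map_estimates],
            }
        )


def _constrain(theta: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unconstrained (..., 3) -> (alpha, rho, beta) arrays."""
    alpha = ndtr(theta[..., 0])
    rho = ndtr(theta[..., 1])
    beta = BETA_SCALE * ndtr(theta[..., 2])
    return alpha, rho, beta


def _session_logliks(theta, choices, feedback, mask=None):
    """Total per-session log-likelihoods for unconstrained theta (..., n, 3).

    ``mask`` selects which trial columns are scored (carry-over windows run
    the recursion over all columns but score a subset).
    """
    alpha, rho, beta = _constrain(theta)
    pw = loglik_trials_batch(choices, feedback, alpha, rho, beta)
    if mask is not None:
        pw = pw[..., mask]
    return pw.sum(axis=-1)


def _log_half_cauchy(sigma: np.ndarray) -> np.ndarray:
    return -np.log1p((sigma / SIGMA_PRIOR_SCALE) ** 2)


def _slice_sample_log_sigma(
    log_sigma: float, n: int, ssq: float, rng: np.random.Generator, width: float = 1.0
) -> float:
    """Univariate stepping-out slice sampler for log sigma.

    Target: product of Normal(theta | mu, sigma) over n participants with
    summed squared deviations ``ssq``, a half-Cauchy(5) prior on sigma,
    and the log-scale Jacobian.
    """

    def logf(ls: float) -> float:
        s2 = math.exp(2.0 * ls)
        return (
            -n * ls
            - 0.5 * ssq / s2
            - math.log1p(s2 / SIGMA_PRIOR_SCALE**2)
            + ls
        )

    y = logf(log_sigma) + math.log(rng.random())
    lo = log_sigma - width * rng.random()
    hi = lo + width
    for _ in range(50):
        if logf(lo) <= y:
            break
        lo -= width
    for _ in range(50):
        if logf(hi) <= y:
            break
        hi += width
    for _ in range(100):
        x = lo + (hi - lo) * rng.random()
        if logf(x) > y:
            return x
        if x < log_sigma:
            lo = x
        else:
            hi = x
    return log_sigma  # pragma: no cover - shrinkage failed to find a point


def _grid_mle_theta(choices, feedback, mask=None) -> np.ndarray:
    """Coarse-grid per-participant ML estimates on the unconstrained scale."""
    from scipy.special import ndtri

    n = choices.shape[0]
    alphas = np.linspace(0.1, 0.9, 7)
    rhos = np.linspace(0.1, 0.9, 7)
    betas = np.array([0.25, 0.5, 1.0, 1.5, 2.0, 3.0, 4.5])
    grid = np.array(
        [(a, r, b) for a in alphas for r in rhos for b in betas]
    )  # (G, 3)
    G = grid.shape[0]
    a = np.repeat(grid[:, 0:1], n, axis=1)
    r = np.repeat(grid[:, 1:2], n, axis=1)
    b = np.repeat(grid[:, 2:3], n, axis=1)
    pw = loglik_trials_batch(choices, feedback, a, r, b)
    if mask is not None:
        pw = pw[..., mask]
    best = grid[pw.sum(axis=-1).argmax(axis=0)]  # (n, 3)
    theta = np.empty((n, 3))
    theta[:, 0] = ndtri(best[:, 0])
    theta[:, 1] = ndtri(best[:, 1])
    theta[:, 2] = ndtri(np.clip(best[:, 2] / BETA_SCALE, 1e-3, 1 - 1e-3))
    return theta


def fit_hierarchical(
    sessions: list[SessionData],
    config: SamplerConfig = SamplerConfig(),
    window: str = "reversal",
) -> PosteriorResult:
    """Fit the hierarchical EWA model to a collection of sessions.

    By default the likelihood uses only each session's reversal-phase
    trials, with the learning state re-initialised at the window start;
    pass ``window='all'`` to fit the full session, or
    ``window='reversal_carryover'`` to score the reversal phase with
    learning state carried over from the discrimination phase.
    """
    if not sessions:
        raise ValueError("need at least one session")
    choices, feedback = sessions_to_arrays(sessions, window)
    mask = None
    if window == "reversal_carryover":
        mask = np.array(
            [
                sessions[0].task.phase_of(t.trial) == "reversal"
                for t in sessions[0].window("all")
            ]
        )
        if not mask.any():
            raise ValueError("no reversal-phase trials to score")
    n, T = choices.shape
    C, D, W = config.chains, config.draws, config.warmup
    rng = np.random.default_rng(config.seed)

    # Initial states: jittered per-participant coarse-grid ML estimates.
    # Unconstrained theta beyond |3| puts alpha/rho/beta on a saturation
    # plateau where the likelihood is flat; chains initialised there (or
    # wandering there early, before proposal scales adapt) can take very
    # long to return. Anchoring every chain near the data-supported region
    # avoids that while the jitter keeps chains overdispersed.
    theta_init = _grid_mle_theta(choices, feedback, mask)
    theta = np.clip(
        theta_init[None, :, :] + 0.4 * rng.standard_normal((C, n, 3)), -2.5, 2.5
    )
    mu = theta.mean(axis=1) + 0.2 * rng.standard_normal((C, 3))
    log_sigma = np.log(theta.std(axis=1) + 0.2) + 0.2 * rng.standard_normal((C, 3))
    ll = _session_logliks(theta, choices, feedback, mask)  # (C, n)

    log_step = np.full((C, n, 3), math.log(0.4))
    acc_count = 0
    acc_total = 0

    theta_draws = np.empty((C, D, n, 3))
    mu_draws = np.empty((C, D, 3))
    sigma_draws = np.empty((C, D, 3))
    logdens_draws = np.empty((C, D))

    def person_log_prior(th, m, ls):
        s = np.exp(ls)
        return (
            -0.5 * (((th - m[:, None, :]) / s[:, None, :]) ** 2).sum(axis=-1)
            - ls.sum(axis=-1)[:, None]
        )

    total_iters = W + D * config.thin
    for it in range(total_iters):
        # --- per-participant random-walk Metropolis on theta, one
        # parameter at a time (cycled), per-parameter adapted scales ---
        for _ in range(config.mh_sweeps):
            for p in range(3):
                prop = theta.copy()
                prop[:, :, p] += np.exp(log_step[:, :, p]) * rng.standard_normal((C, n))
                ll_prop = _session_logliks(prop, choices, feedback, mask)
                sigma_p = np.exp(log_sigma[:, p])[:, None]
                dlp = -0.5 * (
                    ((prop[:, :, p] - mu[:, None, p]) / sigma_p) ** 2
                    - ((theta[:, :, p] - mu[:, None, p]) / sigma_p) ** 2
                )
                accept = np.log(rng.random((C, n))) < (ll_prop - ll) + dlp
                theta = np.where(accept[..., None], prop, theta)
                ll = np.where(accept, ll_prop, ll)
                if it < W:
                    gamma = (it + 1) ** -0.6
                    log_step[:, :, p] += gamma * (
                        accept.astype(float) - config.target_accept
                    )
                else:
                    acc_count += int(accept.sum())
                    acc_total += accept.size

        # --- conjugate Gibbs for mu ---
        sigma2 = np.exp(2.0 * log_sigma)
        prec = 1.0 / MU_PRIOR_SD**2 + n / sigma2
        mean = (theta.sum(axis=1) / sigma2) / prec
        mu = mean + rng.standard_normal((C, 3)) / np.sqrt(prec)

        # --- slice sampling for sigma ---
        ssq = ((theta - mu[:, None, :]) ** 2).sum(axis=1)
        for c in range(C):
            for p in range(3):
                log_sigma[c, p] = _slice_sample_log_sigma(
                    float(log_sigma[c, p]), n, float(ssq[c, p]), rng
                )

        # --- joint translation move per parameter ---
        # Proposal scales mix short and long jumps: weakly identified
        # parameters leave the population location nearly flat over
        # several units and need long-range moves to traverse it.
        for p in range(3):
            scale = rng.choice((0.1, 0.4, 1.6), size=C)
            delta = scale * rng.standard_normal(C)
            prop = theta.copy()
            prop[:, :, p] += delta[:, None]
            mu_prop = mu.copy()
            mu_prop[:, p] += delta
            ll_prop = _session_logliks(prop, choices, feedback, mask)
            log_ratio = (
                (ll_prop - ll).sum(axis=1)
                - 0.5 * (mu_prop[:, p] ** 2 - mu[:, p] ** 2) / MU_PRIOR_SD**2
            )
            accept = np.log(rng.random(C)) < log_ratio
            theta = np.where(accept[:, None, None], prop, theta)
            mu = np.where(accept[:, None], mu_prop, mu)
            ll = np.where(accept[:, None], ll_prop, ll)

        # --- joint rescale move per parameter ---
        for p in range(3):
            log_c = rng.choice((0.1, 0.5), size=C) * rng.standard_normal(C)
            c_fac = np.exp(log_c)
            prop = theta.copy()
            prop[:, :, p] = mu[:, None, p] + c_fac[:, None] * (
                theta[:, :, p] - mu[:, None, p]
            )
            ls_prop = log_sigma.copy()
            ls_prop[:, p] += log_c
            ll_prop = _session_logliks(prop, choices, feedback, mask)
            sigma_old = np.exp(log_sigma[:, p])
            sigma_new = np.exp(ls_prop[:, p])
            # person-level quadratic terms cancel ((theta-mu)/sigma invariant);
            # remaining: -n*log c from the normal normalisers, half-Cauchy
            # prior, +log c from the log-scale Jacobian of sigma, +n*log c
            # from the deterministic theta map's Jacobian.
            log_ratio = (
                (ll_prop - ll).sum(axis=1)
                - n * log_c
                + _log_half_cauchy(sigma_new)
                - _log_half_cauchy(sigma_old)
                + log_c
                + n * log_c
            )
            accept = np.log(rng.random(C)) < log_ratio
            theta = np.where(accept[:, None, None], prop, theta)
            log_sigma = np.where(accept[:, None], ls_prop, log_sigma)
            ll = np.where(accept[:, None], ll_prop, ll)

        if it >= W and (it - W) % config.thin == 0:
            k = (it - W) // config.thin
            theta_draws[:, k] = theta
            mu_draws[:, k] = mu
            sigma_draws[:, k] = np.exp(log_sigma)
            sigma = np.exp(log_sigma)
            logdens_draws[:, k] = (
                ll.sum(axis=1)
                + person_log_prior(theta, mu, log_sigma).sum(axis=1)
                - 0.5 * (mu**2).sum(axis=1) / MU_PRIOR_SD**2
                + _log_half_cauchy(sigma).sum(axis=1)
            )

    # --- diagnostics ---
    # Too few kept draws to split chains: convergence cannot be assessed,
    # which is reported as an infinite R-hat rather than a crash.
    def safe_rhat(x):
        return rhat(x) if x.shape[1] >= 4 else math.inf

    rhats: dict[str, float] = {}
    for p, name in enumerate(_PARAM_NAMES):
        rhats[f"mu_{name}"] = safe_rhat(mu_draws[:, :, p])
        rhats[f"sigma_{name}"] = safe_rhat(sigma_draws[:, :, p])
    theta_rhats = [
        safe_rhat(theta_draws[:, :, i, p]) for i in range(n) for p in range(3)
    ]
    rhats["theta_max"] = float(np.max(theta_rhats))
    converged = all(v < 1.1 for v in rhats.values())
    if not converged:
        warnings.warn(
            f"sampler did not converge: max R-hat = {max(rhats.values()):.3f}",
            stacklevel=2,
        )

    result = PosteriorResult(
        theta=theta_draws,
        mu=mu_draws,
        sigma=sigma_draws,
        log_density=logdens_draws,
        participant_ids=[s.participant_id for s in sessions],
        config=config,
        rhat=rhats,
        converged=converged,
        accept_rate=acc_count / max(acc_total, 1),
    )
    result.map_estimates = map_estimates(result)

    # --- pointwise log-likelihood (subsampled draws) and WAIC ---
    flat_theta = theta_draws.reshape(C * D, n, 3)
    S = min(config.max_pointwise_draws, C * D)
    sel = np.linspace(0, C * D - 1, S).astype(int)
    alpha, rho, beta = _constrain(flat_theta[sel])
    pw = loglik_trials_batch(choices, feedback, alpha, rho, beta)
    if mask is not None:
        pw = pw[..., mask]
    pw = pw.reshape(S, -1)
    result.pointwise_loglik = pw
    result.pointwise_params = np.stack([alpha, rho, beta], axis=-1)
    result.waic = compute_waic(pw)
    return result


def map_estimates(
    result: PosteriorResult, method: str = "mode"
) -> list[EWAParams]:
    """Per-participant MAP point estimates.

    ``method='mode'`` (default) returns, for each participant and
    parameter, the mode of the marginal posterior on the constrained
    scale, located by a Gaussian kernel density estimate over the pooled
    draws. ``method='joint_draw'`` instead returns the constrained values
    of the single kept draw with the highest joint model log-density; that
    variant is simple but inherits one draw's full posterior spread as
    estimation noise, which attenuates any downstream correlation with
    the estimates.
    """
    if result.log_density is None or result.log_density.size == 0:
        raise ValueError("posterior draws carry no joint log-density")
    if method == "joint_draw":
        c, k = np.unravel_index(
            np.argmax(result.log_density), result.log_density.shape
        )
        alpha, rho, beta = _constrain(result.theta[c, k])
        return [
            EWAParams(float(a), float(r), float(b))
            for a, r, b in zip(alpha, rho, beta)
        ]
    if method != "mode":
        raise ValueError(f"unknown MAP method {method!r}")
    from scipy.stats import gaussian_kde

    flat = result.theta.reshape(-1, result.theta.shape[2], 3)
    n_draws = flat.shape[0]
    if n_draws > 1000:  # KDE cost control; the mode is stable well below this
        flat = flat[np.linspace(0, n_draws - 1, 1000).astype(int)]
    alpha, rho, beta = _constrain(flat)
    out = []
    for i in range(flat.shape[1]):
        point = []
        for vals in (alpha[:, i], rho[:, i], beta[:, i]):
            lo, hi = vals.min(), vals.max()
            if hi - lo < 1e-12 or vals.size < 2:
                point.append(float(vals[0]))
                continue
            grid = np.linspace(lo, hi, 256)
            kde = gaussian_kde(vals)
            point.append(float(grid[np.argmax(kde(grid))]))
        out.append(EWAParams(*point))
    return out


def compute_waic(pointwise_loglik: np.ndarray) -> float:
    """Widely-applicable information criterion on the deviance scale.

    ``WAIC = -2 * (lppd - p_waic)`` with the log pointwise predictive
    density ``lppd = sum_obs log mean_draws exp(loglik)`` and the
    variance-form effective parameter count
    ``p_waic = sum_obs var_draws(loglik)``.
    """
    ll = np.asarray(pointwise_loglik, dtype=float)
    if ll.ndim != 2:
        raise ValueError("pointwise_loglik must be draws x observations")
    if not np.all(np.isfinite(ll)):
        raise ValueError("pointwise_loglik contains non-finite entries")
    S = ll.shape[0]
    m = ll.max(axis=0)
    lppd = float(np.sum(m + np.log(np.mean(np.exp(ll - m), axis=0))))
    p_waic = 0.0 if S == 1 else float(np.sum(ll.var(axis=0)))
    return -2.0 * (lppd - p_waic)


def rhat(draws: np.ndarray) -> float:
    """Split-chain potential scale reduction statistic for one quantity.

    ``draws`` is chains x iterations. Each chain is split in half; the
    statistic compares between- and within-half-chain variances. Zero
    total variance returns 1 by convention.
    """
    x = np.asarray(draws, dtype=float)
    if x.ndim != 2 or x.shape[0] < 1 or x.shape[1] < 4:
        raise ValueError("need chains x iterations with at least 4 iterations")
    half = x.shape[1] // 2
    splits = np.concatenate([x[:, :half], x[:, half : 2 * half]], axis=0)
    m, n_it = splits.shape
    chain_means = splits.mean(axis=1)
    w = float(np.mean(splits.var(axis=1, ddof=1)))
    b = float(n_it * chain_means.var(ddof=1))
    if w == 0.0 and b == 0.0:
        return 1.0
    if w == 0.0:
        return math.inf
    var_plus = (n_it - 1) / n_it * w + b / n_it
    return math.sqrt(var_plus / w)
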