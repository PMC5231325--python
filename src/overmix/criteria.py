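"""Criteria for choosing the number of latent classes from MCMC output.

* The non-empty-class criterion (Rousseau & Mengersen style): in each
  retained iteration m count the components whose occupancy fraction
  exceeds a cut-off psi,

      K^(m) = K_max - sum_j 1{ N_j^(m) / N <= psi },

  and select K as the posterior mode of K^(m).  The count is label-
  permutation invariant, so no relabeling of the chain is needed.

* Mixture-adapted deviance information criteria DIC3 (observed-data
  predictive density) and DIC4 (complete-data likelihood with allocation-
  conditioned parameter expectations), minimized over candidate K.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mixture_mcmc import (
    MCMCConfig,
    PosteriorDraws,
    PriorSpecUnivariate,
    run_gibbs_univariate,
)
from .scenarios import UnivariateDataset

__all__ = [
    "ClassCountPosterior",
    "CriterionResult",
    "count_nonempty",
    "posterior_K",
    "dic3",
    "dic3_from_draws",
    "dic4",
    "dic4_from_draws",
    "select_K_by_dic",
]


@dataclass(frozen=True)
class ClassCountPosterior:
    """Distribution of the non-empty-class count across retained iterations."""

    counts_by_K: dict[int, int]
    mode: int
    psi: float

    @property
    def n_iterations(self) -> int:
        return sum(self.counts_by_K.values())

    def probabilities(self) -> dict[int, float]:
        M = self.n_iterations
        return {k: c / M for k, c in sorted(self.counts_by_K.items())}


@dataclass(frozen=True)
class CriterionResult:
    """Outcome of a model-selection criterion."""

    criterion: str  # "RM", "DIC3", "DIC4" or "BIC"
    selected_K: int
    values_by_K: dict[int, float] | None = None
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.selected_K < 1:
            raise ValueError("selected_K must be >= 1")


def count_nonempty(occupancy: np.ndarray, N: int, psi: float) -> int:
    """Number of components whose occupancy fraction exceeds ``psi``.

    A component j is declared empty in this iteration when
    ``N_j / N <= psi`` (non-strict); with ``psi = 0`` only exactly empty
    components are removed.
    """
    occ = np.asarray(occupancy)
    if N <= 0:
        raise ValueError("N must be positive")
    if np.any(occ < 0):
        raise ValueError("occupancy counts must be nonnegative")
    if not (0 <= psi < 1):
        raise ValueError("psi must lie in [0, 1)")
    return int(len(occ) - np.count_nonzero(occ / N <= psi))


def posterior_K(
    occupancy_draws: np.ndarray, N: int, psi: float
) -> ClassCountPosterior:
    """Posterior of the non-empty-class count; mode ties break toward smaller K.

    ``occupancy_draws`` is (M, K_max); each row is one retained iteration's
    occupancy vector.
    """
    occ = np.asarray(occupancy_draws)
    if occ.ndim != 2 or occ.shape[0] == 0:
        raise ValueError("need at least one retained iteration of occupancy draws")
    if N <= 0:
        raise ValueError("N must be positive")
    if np.any(occ < 0):
        raise ValueError("occupancy counts must be nonnegative")
    if not (0 <= psi < 1):
        raise ValueError("psi must lie in [0, 1)")
    K_m = occ.shape[1] - (occ / N <= psi).sum(axis=1)
    ks, counts = np.unique(K_m, return_counts=True)
    # argmax returns the first maximum; ks is sorted ascending => smaller K wins ties
    mode = int(ks[np.argmax(counts)])
    return ClassCountPosterior(
        counts_by_K={int(k): int(c) for k, c in zip(ks, counts)},
        mode=mode,
        psi=psi,
    )


def _log_mean_exp(a: np.ndarray, axis: int) -> np.ndarray:
    mx = np.max(a, axis=axis, keepdims=True)
    out = mx.squeeze(axis) + np.log(np.mean(np.exp(a - mx), axis=axis))
    return out


def dic3(loglik_obs: np.ndarray, obs_logdens: np.ndarray) -> float:
    """DIC3 from per-iteration log-likelihoods and per-observation log densities.

    ``obs_logdens`` is (M, n): log of the mixture density of observation i
    under the iteration-m parameter draw.  The predictive density
    f_hat(y_i) = mean_m f^(m)(y_i) is computed by log-mean-exp over
    iterations, so the two terms are

        DIC3 = -4 mean_m loglik_obs[m] + 2 sum_i log f_hat(y_i).
    """
    loglik_obs = np.asarray(loglik_obs, float)
    ld = np.asarray(obs_logdens, float)
    if ld.ndim != 2 or ld.shape[0] != len(loglik_obs):
        raise ValueError("obs_logdens must be (M, n) matching loglik_obs")
    with np.errstate(invalid="ignore"):
        lme = _log_mean_exp(ld, axis=0)
    if not np.all(np.isfinite(lme)):
        raise ValueError("some observation has zero predictive density in all iterations")
    term1 = -4.0 * float(np.mean(loglik_obs))
    term2 = 2.0 * float(np.sum(lme))
    return term1 + term2


def _obs_logdens_from_draws(
    y: np.ndarray, draws: PosteriorDraws, block: int = 256
) -> np.ndarray:
    """(M, n) log mixture densities recomputed from stored parameter draws."""
    M, n = draws.M, len(y)
    out = np.empty((M, n))
    for start in range(0, M, block):
        sl = slice(start, min(start + block, M))
        lam = np.maximum(draws.lambda_[sl], 1e-300)  # (B, K)
        mu = draws.means[sl]
        var = draws.variances[sl]
        # (B, n, K) log lambda_j + log N(y_i | mu_j, var_j)
        logp = (
            np.log(lam)[:, None, :]
            - 0.5 * (np.log(2 * np.pi * var))[:, None, :]
            - 0.5 * (y[None, :, None] - mu[:, None, :]) ** 2 / var[:, None, :]
        )
        mx = logp.max(axis=2)
        out[sl] = mx + np.log(np.exp(logp - mx[..., None]).sum(axis=2))
    return out


def dic3_from_draws(data: UnivariateDataset | np.ndarray, draws: PosteriorDraws) -> float:
    """Convenience wrapper: DIC3 recomputing observation densities from draws."""
    y = np.asarray(data.values if isinstance(data, UnivariateDataset) else data, float)
    return dic3(draws.loglik_obs, _obs_logdens_from_draws(y, draws))


def _trunc_invgamma_mean(
    counts: np.ndarray, ss: np.ndarray, lower: float, upper: float, n_grid: int = 1024
) -> np.ndarray:
    """E[sigma^2] for the kernel (s2)^(-N/2) exp(-SS/(2 s2)) on (lower, upper).

    Proper for every N >= 0 thanks to the bounded support (N=0 reduces to the
    uniform prior mean).  Evaluated on a log-density grid, vectorized over
    classes.
    """
    u_hi = np.log(upper)
    u_lo = np.log(lower) if lower > 0 else u_hi - 46.0
    grid_u = np.linspace(u_lo, u_hi, n_grid)  # (G,) on u = log sigma^2
    # Jacobian e^u folded in: log f_u = (1 - N/2) u - (SS/2) e^-u
    logd = (1.0 - counts[:, None] / 2.0) * grid_u[None, :] - (
        ss[:, None] / 2.0
    ) * np.exp(-grid_u)[None, :]
    logd -= logd.max(axis=1, keepdims=True)
    w = np.exp(logd)
    w[:, [0, -1]] *= 0.5  # trapezoid end-weights (uniform grid spacing)
    return (w * np.exp(grid_u)).sum(axis=1) / w.sum(axis=1)


def _conditional_posterior_means(
    y: np.ndarray,
    z: np.ndarray,
    K: int,
    prior: PriorSpecUnivariate,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Closed-form E[theta | y, Z=z] under the model's conjugate structure.

    Returns (lambda_bar, mu_bar, var_bar): the Dirichlet posterior mean of
    the proportions; a posterior point value for each class variance from
    the inverse-gamma kernel given z (truncated to (lower, upper) under the
    uniform prior, so it is proper for any occupancy including empty); and
    the conjugate-normal posterior mean of each class mean with the variance
    profiled at var_bar.  Components empty under z take their prior means.
    """
    n = len(y)
    counts = np.bincount(z, minlength=K).astype(float)
    sums = np.bincount(z, weights=y, minlength=K)
    sqsums = np.bincount(z, weights=y * y, minlength=K)

    lam_bar = (prior.alpha + counts) / (K * prior.alpha + n)

    # within-class sum of squares about the class MLE mean
    with np.errstate(invalid="ignore", divide="ignore"):
        mle_mean = np.where(counts > 0, sums / np.maximum(counts, 1.0), 0.0)
    ss = np.maximum(sqsums - counts * mle_mean**2, 0.0)

    if prior.var_prior == "hierarchical":
        # tau ~ Gamma(beta1 + N/2, rate0 + SS/2) => E[sigma^2] = rate/(shape-1)
        rate0 = 1.0  # C0 profiled at a unit rate for the conditional mean
        shape = prior.beta1 + counts / 2.0
        var_bar = (rate0 + ss / 2.0) / np.maximum(shape - 1.0, 0.25)
    else:
        var_bar = _trunc_invgamma_mean(counts, ss, prior.var_lower, prior.var_upper)

    m0, v0 = prior.mean0, prior.var0
    post_prec = counts / var_bar + 1.0 / v0
    mu_bar = (sums / var_bar + m0 / v0) / post_prec
    mu_bar = np.where(counts > 0, mu_bar, m0)
    return lam_bar, mu_bar, var_bar


def _complete_loglik(
    y: np.ndarray, z: np.ndarray, lam: np.ndarray, mu: np.ndarray, var: np.ndarray
) -> float:
    with np.errstate(divide="ignore"):
        ll = (
            np.log(np.maximum(lam, 1e-300))[z]
            - 0.5 * np.log(2 * np.pi * var[z])
            - 0.5 * (y - mu[z]) ** 2 / var[z]
        )
    return float(ll.sum())


def dic4(
    loglik_complete: np.ndarray,
    y: np.ndarray,
    allocations: np.ndarray,
    prior: PriorSpecUnivariate,
    K: int,
) -> float:
    """DIC4 from complete-data log-likelihoods and stored allocations.

    First term: -4 mean_m loglik_complete[m].  Second term: for each stored
    allocation vector z^(m), evaluate the complete-data log-likelihood at
    E[theta | y, Z=z^(m)] (conjugate closed forms) and average:

        DIC4 = -4 E[log f(y,Z|theta)] + 2 E_Z[log f(y,Z | E[theta|y,Z])].
    """
    if allocations is None or len(allocations) == 0:
        raise ValueError("DIC4 requires stored allocations")
    term1 = -4.0 * float(np.mean(np.asarray(loglik_complete, float)))
    vals = np.empty(len(allocations))
    for m, z in enumerate(allocations):
        z = np.asarray(z, dtype=np.int64)
        lam_bar, mu_bar, var_bar = _conditional_posterior_means(y, z, K, prior)
        vals[m] = _complete_loglik(y, z, lam_bar, mu_bar, var_bar)
    return term1 + 2.0 * float(vals.mean())


def dic4_from_draws(
    data: UnivariateDataset | np.ndarray,
    draws: PosteriorDraws,
    prior: PriorSpecUnivariate,
) -> float:
    """Convenience wrapper for :func:`dic4` on a finished chain."""
    y = np.asarray(data.values if isinstance(data, UnivariateDataset) else data, float)
    if draws.allocation_thin > 1:
        loglik_complete = draws.loglik_complete[:: draws.allocation_thin]
    else:
        loglik_complete = draws.loglik_complete
    return dic4(loglik_complete, y, draws.allocations, prior, draws.K_max)


def select_K_by_dic(
    data: UnivariateDataset | np.ndarray,
    K_range,
    prior: PriorSpecUnivariate,
    config: MCMCConfig,
    which: str = "DIC3",
) -> CriterionResult:
    """Fit one (non-overfitted) mixture per candidate K and minimize the DIC.

    The same Gibbs machinery is used with ``K_max = K``; ties in the minimum
    break toward smaller K.
    """
    K_range = sorted(set(int(k) for k in K_range))
    if not K_range:
        raise ValueError("K_range must be nonempty")
    if which not in ("DIC3", "DIC4"):
        raise ValueError("which must be 'DIC3' or 'DIC4'")
    values: dict[int, float] = {}
    for K in K_range:
        cfg_k = MCMCConfig(
            K_max=max(K, 1),
            n_iter=config.n_iter,
            burn_in=config.burn_in,
            seed=config.seed,
            store_allocations=which == "DIC4" or None,
            allocation_thin=config.allocation_thin,
        )
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", UserWarning)  # alpha >= d/2 is deliberate here
            draws = run_gibbs_univariate(data, prior, cfg_k)
        if which == "DIC3":
            values[K] = dic3_from_draws(data, draws)
        else:
            values[K] = dic4_from_draws(data, draws, prior)
    best = min(values, key=lambda k: (values[k], k))
    return CriterionResult(criterion=which, selected_K=best, values_by_K=values)
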