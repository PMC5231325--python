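"""Maximum-likelihood fitting of mixtures by EM, and BIC-based selection.

Univariate Gaussian mixtures use the classical EM closed forms with a
variance floor guarding the unbounded-likelihood spikes.  Growth mixtures
(latent-class linear mixed models) use EM over both latent quantities --
class membership and subject random effects -- with the random effects
handled through their conditional Gaussian moments, so the marginal
likelihood (random effects integrated out) increases monotonically.

Multiple starts follow the usual short-run strategy: every start runs a
small number of EM iterations, the best is continued to convergence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .criteria import CriterionResult
from .growth_mcmc import GrowthModelSpec, _PreparedData
from .scenarios import LongitudinalDataset, UnivariateDataset

__all__ = ["MLEFit", "em_univariate", "em_growth", "bic", "select_K_bic"]


@dataclass
class MLEFit:
    """Result of a maximum-likelihood mixture fit."""

    K: int
    params: dict
    loglik: float
    g: int  # free parameters
    n: int  # observations entering the BIC penalty
    converged: bool
    n_starts: int
    loglik_trace: np.ndarray | None = None


def bic(loglik: float, g: int, n: int) -> float:
    """Bayesian information criterion: -2 loglik + g log(n)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return -2.0 * loglik + g * np.log(n)


def _em_univariate_once(
    y: np.ndarray,
    K: int,
    lam: np.ndarray,
    mu: np.ndarray,
    var: np.ndarray,
    tol: float,
    max_iter: int,
    var_floor: float,
):
    n = len(y)
    prev = -np.inf
    trace = []
    converged = False
    for _ in range(max_iter):
        # E-step in log space
        with np.errstate(divide="ignore"):
            logp = (
                np.log(np.maximum(lam, 1e-300))[None, :]
                - 0.5 * np.log(2 * np.pi * var)[None, :]
                - 0.5 * (y[:, None] - mu[None, :]) ** 2 / var[None, :]
            )
        mx = logp.max(axis=1)
        lse = mx + np.log(np.exp(logp - mx[:, None]).sum(axis=1))
        ll = float(lse.sum())
        trace.append(ll)
        r = np.exp(logp - lse[:, None])
        # M-step
        nk = r.sum(axis=0)
        lam = nk / n
        mu = (r * y[:, None]).sum(axis=0) / np.maximum(nk, 1e-300)
        var = (r * (y[:, None] - mu[None, :]) ** 2).sum(axis=0) / np.maximum(
            nk, 1e-300
        )
        var = np.maximum(var, var_floor)
        if np.isfinite(prev) and abs(ll - prev) <= tol * (abs(prev) + 1.0):
            converged = True
            break
        prev = ll
    return lam, mu, var, trace[-1], np.asarray(trace), converged


def em_univariate(
    data: UnivariateDataset | np.ndarray,
    K: int,
    n_starts: int = 10,
    tol: float = 1e-6,
    max_iter: int = 500,
    seed: int = 0,
) -> MLEFit:
    """Best-of-``n_starts`` EM fit of a K-component univariate Gaussian mixture.

    Starts are quantile-based means with random perturbation; a variance
    floor of 1e-6 times the sample variance prevents degenerate spikes.
    """
    y = np.asarray(data.values if isinstance(data, UnivariateDataset) else data, float)
    n = len(y)
    if K < 1:
        raise ValueError("K must be >= 1")
    if n <= K:
        raise ValueError("need more observations than components")
    rng = np.random.default_rng(seed)
    svar = float(np.var(y))
    var_floor = 1e-6 * max(svar, 1e-300)

    if K == 1:
        mu = float(np.mean(y))
        ll = float(
            np.sum(-0.5 * np.log(2 * np.pi * svar) - 0.5 * (y - mu) ** 2 / svar)
        )
        return MLEFit(
            K=1,
            params={"proportions": np.ones(1), "means": np.array([mu]), "variances": np.array([svar])},
            loglik=ll,
            g=2,
            n=n,
            converged=True,
            n_starts=1,
        )

    base_mu = np.quantile(y, (np.arange(K) + 0.5) / K)
    spread = float(np.std(y))
    short = []
    for s in range(n_starts):
        mu0 = base_mu + (0.0 if s == 0 else rng.normal(0, 0.25 * spread, K))
        lam0 = np.full(K, 1.0 / K)
        var0 = np.full(K, svar)
        short.append(
            _em_univariate_once(y, K, lam0, mu0, var0, tol, 30, var_floor)
        )
    best = max(range(n_starts), key=lambda s: short[s][3])
    lam, mu, var, ll, trace0, conv = short[best]
    lam, mu, var, ll, trace, conv = _em_univariate_once(
        y, K, lam, mu, var, tol, max_iter, var_floor
    )
    return MLEFit(
        K=K,
        params={"proportions": lam, "means": mu, "variances": var},
        loglik=ll,
        g=3 * K - 1,
        n=n,
        converged=conv,
        n_starts=n_starts,
        loglik_trace=np.concatenate([trace0, trace]),
    )


def _growth_estep(prep: _PreparedData, lam, theta, gamma, Sigma, sigma2):
    """Responsibilities, marginal loglik and conditional random-effect moments.

    Returns (loglik, r (n,K), Eb (n,K,q), A (K,q,q per group list)).
    """
    K = len(lam)
    n = prep.n_subjects
    q = prep.q
    c = prep.c
    logp = np.empty((n, K))
    Eb = np.empty((n, K, q))
    A_by_group = []
    Sigma_inv = np.linalg.inv(Sigma)
    for g in prep.groups:
        Z = g["Z"]
        T_g = Z.shape[0]
        fixed = np.einsum("itp,jp->ijt", g["X"], theta)
        if c:
            fixed = fixed + (g["W"] @ gamma)[:, None, :]
        R = g["Y"][:, None, :] - fixed  # (n_g, K, T)
        V = np.einsum("tq,kqr,sr->kts", Z, Sigma, Z) + sigma2 * np.eye(T_g)
        Lv = np.linalg.cholesky(V)
        u = np.linalg.solve(Lv, R.transpose(1, 2, 0))  # (K, T, n_g)
        quad = np.einsum("kti,kti->ki", u, u)
        logdet = 2.0 * np.sum(np.log(np.diagonal(Lv, axis1=1, axis2=2)), axis=1)
        logp[g["idx"], :] = (
            -0.5 * (T_g * np.log(2 * np.pi) + logdet[:, None] + quad)
        ).T
        A = np.linalg.inv(g["ZtZ"][None] / sigma2 + Sigma_inv)  # (K,q,q)
        A_by_group.append(A)
        Ztr = np.einsum("ikt,tq->ikq", R, Z) / sigma2
        Eb[g["idx"]] = np.einsum("kqr,ikr->ikq", A, Ztr)
    with np.errstate(divide="ignore"):
        logp += np.log(np.maximum(lam, 1e-300))[None, :]
    mx = logp.max(axis=1)
    lse = mx + np.log(np.exp(logp - mx[:, None]).sum(axis=1))
    loglik = float(lse.sum())
    r = np.exp(logp - lse[:, None])
    return loglik, r, Eb, A_by_group


def _growth_mstep(prep: _PreparedData, r, Eb, A_by_group, theta, gamma, shared_cov):
    """One ECM cycle given the E-step moments; returns updated parameters."""
    K = r.shape[1]
    p, c, q = prep.p, prep.c, prep.q
    n = prep.n_subjects

    lam = r.mean(axis=0)
    nk = r.sum(axis=0)

    # theta_j: weighted least squares with E[b] plugged in
    XtX_k = np.zeros((K, p, p))
    Xr_k = np.zeros((K, p))
    for gi, g in enumerate(prep.groups):
        idx = g["idx"]
        base = g["Y"][:, None, :] - np.einsum("ikq,tq->ikt", Eb[idx], g["Z"])
        if c:
            base = base - (g["W"] @ gamma)[:, None, :]
        XtX_k += np.einsum("ik,ipr->kpr", r[idx], g["XtX"])
        Xr_k += np.einsum("ik,itp,ikt->kp", r[idx], g["X"], base)
    # tiny ridge keeps the solve well-posed when a class loses all weight
    theta = np.linalg.solve(XtX_k + 1e-10 * np.eye(p)[None], Xr_k[..., None])[..., 0]

    if c:
        WtW = np.zeros((c, c))
        Wr = np.zeros(c)
        for g in prep.groups:
            idx = g["idx"]
            base = (
                g["Y"][:, None, :]
                - np.einsum("jp,itp->ijt", theta, g["X"])
                - np.einsum("ikq,tq->ikt", Eb[idx], g["Z"])
            )
            WtW += g["WtW"]  # sum_j r_ij = 1
            Wr += np.einsum("ik,itc,ikt->c", r[idx], g["W"], base)
        gamma = np.linalg.solve(WtW, Wr)

    # Sigma_j = sum_i r_ij (E[b]E[b]' + A_j) / sum_i r_ij, or the pooled
    # average across classes when the covariance is shared (lcmm-style)
    Sigma = np.zeros((K, q, q))
    for gi, g in enumerate(prep.groups):
        idx = g["idx"]
        outer = np.einsum("ikq,ikr->ikqr", Eb[idx], Eb[idx])
        Sigma += np.einsum("ik,ikqr->kqr", r[idx], outer)
        Sigma += nk_group(r[idx])[:, None, None] * A_by_group[gi]
    if shared_cov:
        Sigma = np.tile(Sigma.sum(axis=0) / n, (K, 1, 1))
    else:
        Sigma /= np.maximum(nk, 1e-300)[:, None, None]
    Sigma += 1e-10 * np.eye(q)[None]

    # sigma^2 with the trace correction tr(Z A_j Z')
    rss = 0.0
    for gi, g in enumerate(prep.groups):
        idx = g["idx"]
        resid = (
            g["Y"][:, None, :]
            - np.einsum("jp,itp->ijt", theta, g["X"])
            - np.einsum("ikq,tq->ikt", Eb[idx], g["Z"])
        )
        if c:
            resid = resid - (g["W"] @ gamma)[:, None, :]
        rss += float(np.einsum("ik,ikt,ikt->", r[idx], resid, resid))
        tr = np.einsum("tq,kqr,tr->k", g["Z"], A_by_group[gi], g["Z"])
        rss += float(nk_group(r[idx]) @ tr)
    sigma2 = max(rss / prep.n_rows, 1e-10)
    return lam, theta, gamma, Sigma, sigma2


def nk_group(r_g: np.ndarray) -> np.ndarray:
    return r_g.sum(axis=0)


def _em_growth_once(prep, lam, theta, gamma, Sigma, sigma2, tol, max_iter, shared_cov=True):
    prev = -np.inf
    trace = []
    converged = False
    for _ in range(max_iter):
        ll, r, Eb, A = _growth_estep(prep, lam, theta, gamma, Sigma, sigma2)
        trace.append(ll)
        if np.isfinite(prev) and abs(ll - prev) <= tol * (abs(prev) + 1.0):
            converged = True
            break
        prev = ll
        lam, theta, gamma, Sigma, sigma2 = _growth_mstep(
            prep, r, Eb, A, theta, gamma, shared_cov
        )
    return (lam, theta, gamma, Sigma, sigma2), trace[-1], np.asarray(trace), converged


def em_growth(
    data: LongitudinalDataset | pd.DataFrame,
    K: int,
    model: GrowthModelSpec,
    n_starts: int = 10,
    tol: float = 1e-6,
    max_iter: int = 500,
    seed: int = 0,
    bic_n: str = "rows",
    shared_cov: bool = True,
) -> MLEFit:
    """Best-of-``n_starts`` EM fit of a K-class linear mixed growth mixture.

    ``bic_n`` chooses the BIC sample size: total observation rows
    (``"rows"``, the common mixed-model convention) or ``"subjects"``.
    ``shared_cov`` pools the random-effect covariance across classes
    (the default of the usual frequentist latent-class mixed-model fitters);
    set it False for a class-specific covariance matching the Bayesian
    sampler's parameterization.
    """
    prep = _PreparedData(data, model)
    if K < 1:
        raise ValueError("K must be >= 1")
    rng = np.random.default_rng(seed)
    p, c, q = prep.p, prep.c, prep.q

    y_cat = np.concatenate([g["Y"].ravel() for g in prep.groups])
    X_cat = np.concatenate([g["X"].reshape(-1, p) for g in prep.groups])
    if c:
        W_cat = np.concatenate([g["W"].reshape(-1, c) for g in prep.groups])
        D = np.hstack([X_cat, W_cat])
    else:
        D = X_cat
    coef, *_ = np.linalg.lstsq(D, y_cat, rcond=None)
    theta0, gamma0 = coef[:p], coef[p:]
    resid_var = max(float(np.var(y_cat - D @ coef)), 1e-8)
    subj_means = np.concatenate([g["Y"].mean(axis=1) for g in prep.groups])
    try:
        i0 = model.class_specific_terms.index("intercept")
    except ValueError:
        i0 = 0

    def start(s: int):
        theta = np.tile(theta0, (K, 1))
        offs = np.quantile(subj_means, (np.arange(K) + 0.5) / K) - subj_means.mean()
        if s > 0:
            offs = offs + rng.normal(0, 0.25 * subj_means.std() + 1e-12, K)
        theta[:, i0] += offs
        lam = np.full(K, 1.0 / K)
        Sigma = np.tile(np.eye(q) * max(0.1 * resid_var, 1e-6), (K, 1, 1))
        return lam, theta, gamma0.copy(), Sigma, 0.5 * resid_var

    short = [
        _em_growth_once(prep, *start(s), tol, 30, shared_cov) for s in range(n_starts)
    ]
    best = max(range(n_starts), key=lambda s: short[s][1])
    params, ll, trace0, conv = _em_growth_once(
        prep, *short[best][0], tol, max_iter, shared_cov
    )
    lam, theta, gamma, Sigma, sigma2 = params
    n_cov = q * (q + 1) // 2 if shared_cov else K * q * (q + 1) // 2
    g_free = K * p + n_cov + c + 1 + (K - 1)
    n_pen = prep.n_rows if bic_n == "rows" else prep.n_subjects
    return MLEFit(
        K=K,
        params={
            "proportions": lam,
            "theta": theta,
            "gamma": gamma,
            "Sigma": Sigma,
            "resid_var": sigma2,
        },
        loglik=ll,
        g=g_free,
        n=n_pen,
        converged=conv,
        n_starts=n_starts,
        loglik_trace=np.concatenate([short[best][2], trace0]),
    )


def select_K_bic(data, K_range, fitter) -> CriterionResult:
    """Fit each candidate K with ``fitter(data, K) -> MLEFit``; argmin BIC.

    Ties break toward smaller K.
    """
    K_range = sorted(set(int(k) for k in K_range))
    if not K_range:
        raise ValueError("K_range must be nonempty")
    values: dict[int, float] = {}
    for K in K_range:
        fit = fitter(data, K)
        values[K] = bic(fit.loglik, fit.g, fit.n)
    best = min(values, key=lambda k: (values[k], k))
    return CriterionResult(criterion="BIC", selected_K=best, values_by_K=values)
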