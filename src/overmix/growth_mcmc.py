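"""Gibbs sampler for overfitted latent-class linear mixed models.

Growth mixture model: subject i in class j has

    y_it = x_it' theta_j + w_it' gamma + z_it' b_i + eps_it,

with class-specific fixed effects theta_j, common fixed effects gamma,
subject random effects b_i ~ N(0, Sigma_j) with a class-specific covariance,
and iid residuals eps_it ~ N(0, sigma^2).  The model is overfitted with
K_max classes and a sparse symmetric Dirichlet(alpha) prior on the class
proportions; the subject-level occupancy counts recorded per iteration feed
the non-empty-class selection criterion.

Subject allocation uses the marginal likelihood with the random effects
integrated out analytically,

    y_i | z_i = j  ~  MVN( X_i theta_j + W_i gamma,  Z_i Sigma_j Z_i' + sigma^2 I ),

which mixes considerably better than conditioning on the current b_i draws
(the conditional route is retained for cross-checking).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular

from .mixture_mcmc import MCMCConfig, sample_proportions
from .scenarios import LongitudinalDataset

__all__ = [
    "PriorSpecGrowth",
    "GrowthModelSpec",
    "GrowthPosteriorDraws",
    "subject_allocation_probs",
    "run_gibbs_growth",
    "default_alpha",
]


@dataclass(frozen=True)
class PriorSpecGrowth:
    """Prior hierarchy for the latent-class linear mixed model.

    Fixed effects get independent N(0, fixed_effect_var) priors; the residual
    precision gets Gamma(resid_shape, resid_rate) (i.e. an inverse-gamma on
    the variance); the class-specific random-effect covariance gets an
    inverse-Wishart with ``re_df`` degrees of freedom and scale
    ``re_scale * I`` when the random-effect dimension is >= 2, or a
    Gamma(re_prec_shape, re_prec_rate) prior on the random-intercept
    precision in the intercept-only model.
    """

    alpha: float
    fixed_effect_var: float = 1e3
    resid_shape: float = 1e-3
    resid_rate: float = 1e-3
    re_df: float = 3.0
    re_scale: float = 1e-3
    re_prec_shape: float = 1e-3
    re_prec_rate: float = 1e-3

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        for name in (
            "fixed_effect_var",
            "resid_shape",
            "resid_rate",
            "re_df",
            "re_scale",
            "re_prec_shape",
            "re_prec_rate",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class GrowthModelSpec:
    """Which design columns are class-specific, common, and random.

    Term names refer to columns of the long-format data frame; the special
    name ``"intercept"`` denotes a column of ones.  ``d`` counts the
    class-specific parameters (fixed effects plus free covariance entries),
    which sets the sparse-Dirichlet validity threshold alpha < d/2.
    """

    class_specific_terms: tuple[str, ...] = ("intercept", "time")
    common_terms: tuple[str, ...] = ()
    random_terms: tuple[str, ...] = ("intercept", "time")

    def __post_init__(self) -> None:
        if not self.class_specific_terms:
            raise ValueError("need at least one class-specific term")
        if not self.random_terms:
            raise ValueError("need at least one random term")

    @property
    def q(self) -> int:
        return len(self.random_terms)

    @property
    def d(self) -> int:
        return len(self.class_specific_terms) + self.q * (self.q + 1) // 2


def default_alpha(model: GrowthModelSpec, fraction: float = 0.85) -> float:
    """Recommended Dirichlet hyperparameter: a stated fraction of d/2.

    Simulation evidence favors alpha slightly below the validity threshold
    d/2 (around 0.8-0.9 of it) for vague class-specific priors.
    """
    return fraction * model.d / 2.0


@dataclass
class GrowthPosteriorDraws:
    """Retained per-iteration state of the growth-mixture chain."""

    lambda_: np.ndarray  # (M, K)
    theta: np.ndarray  # (M, K, p) class-specific fixed effects
    gamma: np.ndarray  # (M, c) common fixed effects (c may be 0)
    Sigma: np.ndarray  # (M, K, q, q) random-effect covariances
    resid_var: np.ndarray  # (M,)
    counts: np.ndarray  # (M, K) subject occupancy
    loglik_obs: np.ndarray  # (M,) marginal (b integrated out) log-likelihood
    n_subjects: int
    allocations: np.ndarray | None = None  # (M, n_subjects) int16

    @property
    def M(self) -> int:
        return self.lambda_.shape[0]

    @property
    def K_max(self) -> int:
        return self.lambda_.shape[1]


def _design_column(frame: pd.DataFrame, term: str) -> np.ndarray:
    if term == "intercept":
        return np.ones(len(frame))
    if term not in frame.columns:
        raise ValueError(f"design term {term!r} is not a column of the data")
    return frame[term].to_numpy(dtype=float)


class _PreparedData:
    """Subjects grouped by shared random-effect design for vectorized updates.

    Balanced simulated data form a single group, giving one Cholesky per
    (group, class) in the allocation step instead of one per subject.
    """

    def __init__(self, data: LongitudinalDataset | pd.DataFrame, model: GrowthModelSpec):
        frame = data.frame if isinstance(data, LongitudinalDataset) else data
        for col in ("subject_id", "y"):
            if col not in frame.columns:
                raise ValueError(f"data must contain a {col!r} column")
        self.model = model
        sids = frame["subject_id"].to_numpy()
        self.subject_ids = np.unique(sids)
        self.n_subjects = len(self.subject_ids)
        if self.n_subjects < 1:
            raise ValueError("need at least one subject")
        self.n_rows = len(frame)

        p, c, q = len(model.class_specific_terms), len(model.common_terms), model.q
        X_all = np.column_stack(
            [_design_column(frame, t) for t in model.class_specific_terms]
        )
        W_all = (
            np.column_stack([_design_column(frame, t) for t in model.common_terms])
            if c
            else np.zeros((len(frame), 0))
        )
        Z_all = np.column_stack([_design_column(frame, t) for t in model.random_terms])
        y_all = frame["y"].to_numpy(dtype=float)

        order = np.argsort(sids, kind="stable")
        sids_o = sids[order]
        bounds = np.flatnonzero(np.r_[True, sids_o[1:] != sids_o[:-1], True])

        per_subject = []
        for s in range(self.n_subjects):
            rows = order[bounds[s] : bounds[s + 1]]
            per_subject.append(
                (y_all[rows], X_all[rows], W_all[rows], Z_all[rows])
            )

        keys: dict[bytes, int] = {}
        groups: list[dict] = []
        for s, (y_i, X_i, W_i, Z_i) in enumerate(per_subject):
            key = np.ascontiguousarray(Z_i).tobytes() + bytes([len(y_i)])
            g = keys.setdefault(key, len(keys))
            if g == len(groups):
                groups.append({"subjects": [], "Z": Z_i})
            groups[g]["subjects"].append(s)
        self.group_of = np.empty(self.n_subjects, dtype=np.int64)
        self.groups = []
        for g, grp in enumerate(groups):
            idx = np.asarray(grp["subjects"])
            self.group_of[idx] = g
            Y = np.stack([per_subject[s][0] for s in idx])
            X = np.stack([per_subject[s][1] for s in idx])
            W = np.stack([per_subject[s][2] for s in idx])
            Z = grp["Z"]
            self.groups.append(
                {
                    "idx": idx,
                    "Y": Y,  # (n_g, T)
                    "X": X,  # (n_g, T, p)
                    "W": W,  # (n_g, T, c)
                    "Z": Z,  # (T, q)
                    "ZtZ": Z.T @ Z,
                    "XtX": np.einsum("itp,itr->ipr", X, X),  # (n_g, p, p)
                    "WtW": np.einsum("itc,itd->cd", W, W),  # (c, c)
                }
            )
        self.p, self.c, self.q = p, c, q


def _mvn_group_logpdf(R: np.ndarray, V_chol: np.ndarray) -> np.ndarray:
    """Log MVN(0, V) density of each row of R given chol(V) (lower)."""
    T = R.shape[1]
    u = solve_triangular(V_chol, R.T, lower=True)
    quad = np.einsum("ti,ti->i", u, u)
    logdet = 2.0 * np.sum(np.log(np.diag(V_chol)))
    return -0.5 * (T * np.log(2 * np.pi) + logdet + quad)


def subject_allocation_probs(
    y_i: np.ndarray,
    X_i: np.ndarray,
    W_i: np.ndarray | None,
    Z_i: np.ndarray,
    lam: np.ndarray,
    thetas: np.ndarray,
    gamma: np.ndarray | None,
    Sigmas: np.ndarray,
    resid_var: float,
) -> np.ndarray:
    """Posterior class probabilities for one subject, random effects
    integrated out:

        p_j ∝ lambda_j MVN(y_i | X_i theta_j + W_i gamma, Z_i Sigma_j Z_i' + sigma^2 I).
    """
    y_i = np.asarray(y_i, float)
    T = len(y_i)
    K = len(lam)
    common = W_i @ gamma if (W_i is not None and gamma is not None and len(gamma)) else 0.0
    logp = np.empty(K)
    for j in range(K):
        V = Z_i @ Sigmas[j] @ Z_i.T + resid_var * np.eye(T)
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError("singular marginal covariance") from err
        r = y_i - X_i @ thetas[j] - common
        logp[j] = _mvn_group_logpdf(r[None, :], L)[0]
    with np.errstate(divide="ignore"):
        logp = logp + np.log(np.maximum(np.asarray(lam, float), 1e-300))
    logp -= logp.max()
    pr = np.exp(logp)
    return pr / pr.sum()


def _invwishart_batch(
    df: np.ndarray, scales: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Batched inverse-Wishart draws via Bartlett, one per leading index.

    ``df`` is (K,) and ``scales`` is (K, q, q).  Convention: density
    ∝ |Sigma|^{-(df+q+1)/2} exp(-tr(scale Sigma^{-1})/2), i.e.
    Sigma^{-1} ~ Wishart(df, scale^{-1}).
    """
    K, q, _ = scales.shape
    L = np.linalg.cholesky(np.linalg.inv(scales))
    A = np.zeros((K, q, q))
    i = np.arange(q)
    A[:, i, i] = np.sqrt(rng.chisquare(np.asarray(df)[:, None] - i[None, :]))
    if q > 1:
        tr, tc = np.tril_indices(q, k=-1)
        A[:, tr, tc] = rng.standard_normal((K, len(tr)))
    W = L @ A
    prec = W @ W.transpose(0, 2, 1)
    return np.linalg.inv(prec)


def _draw_mvn(mean: np.ndarray, cov: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    L = np.linalg.cholesky(cov)
    return mean + L @ rng.standard_normal(len(mean))


# Bounds keeping empty-class covariance draws finite: the vague
# Gamma(1e-3, 1e-3) / IW(diag(1e-3), 3) priors are so diffuse that draws for
# classes with no members routinely under/overflow float64 (variance 0 or
# inf), which would break the Cholesky in the allocation step.  Occupied
# classes never come near these bounds.
_VAR_FLOOR = 1e-10
_VAR_CEIL = 1e6


def _stabilize_cov(S: np.ndarray) -> np.ndarray:
    d = np.diag(S)
    if not np.all(np.isfinite(S)) or d.max() > _VAR_CEIL:
        top = np.nanmax(d[np.isfinite(d)]) if np.any(np.isfinite(d)) else np.inf
        if not np.isfinite(top) or top <= 0:
            return np.eye(S.shape[0]) * _VAR_CEIL
        S = np.where(np.isfinite(S), S, 0.0) * (_VAR_CEIL / max(top, _VAR_CEIL))
    if np.diag(S).min() < _VAR_FLOOR:
        S = S + _VAR_FLOOR * np.eye(S.shape[0])
    return S


def run_gibbs_growth(
    data: LongitudinalDataset | pd.DataFrame,
    model: GrowthModelSpec,
    prior: PriorSpecGrowth,
    config: MCMCConfig,
    marginal_allocation: bool = True,
) -> GrowthPosteriorDraws:
    """Blocked Gibbs sampler for the overfitted growth mixture.

    Block order within one cycle: subject allocations (marginal likelihood)
    -> proportions -> subject random effects -> class fixed effects ->
    common fixed effects -> random-effect covariances -> residual precision.
    As in the univariate sampler, the loop is rotated so that stored
    allocations and log-likelihoods correspond to the stored parameters.

    With ``marginal_allocation=False`` subjects are allocated conditioning
    on the freshly drawn random effects instead; this exists to cross-check
    the analytic marginalization and is not the default.
    """
    prep = _PreparedData(data, model)
    if prior.alpha >= model.d / 2:
        warnings.warn(
            f"alpha={prior.alpha} is at or above d/2={model.d / 2}: superfluous "
            "classes are no longer guaranteed to empty asymptotically",
            UserWarning,
            stacklevel=2,
        )
    K = config.K_max
    p, c, q = prep.p, prep.c, prep.q
    n = prep.n_subjects
    rng = np.random.default_rng(config.seed)

    # --- initialization -------------------------------------------------
    # pooled OLS for all fixed effects; class intercept-like spread comes
    # from quantiles of subject-level mean responses to avoid class death
    y_cat = np.concatenate([g["Y"].ravel() for g in prep.groups])
    X_cat = np.concatenate([g["X"].reshape(-1, p) for g in prep.groups])
    if c:
        W_cat = np.concatenate([g["W"].reshape(-1, c) for g in prep.groups])
        D = np.hstack([X_cat, W_cat])
    else:
        D = X_cat
    coef, *_ = np.linalg.lstsq(D, y_cat, rcond=None)
    theta0, gamma0 = coef[:p], coef[p:]
    subj_means = np.empty(n)
    for g in prep.groups:
        subj_means[g["idx"]] = g["Y"].mean(axis=1)
    offsets = np.quantile(subj_means, np.linspace(0.1, 0.9, K)) - subj_means.mean()
    theta = np.tile(theta0, (K, 1))
    try:
        i0 = model.class_specific_terms.index("intercept")
    except ValueError:
        i0 = 0
    theta[:, i0] += offsets
    gamma = gamma0.copy()
    resid = y_cat - D @ coef
    sigma2 = max(float(np.var(resid)), 1e-8)
    Sigma = np.tile(np.eye(q) * max(0.1 * sigma2, 1e-4), (K, 1, 1))
    lam = np.full(K, 1.0 / K)
    # initial allocation: quantile bins of the subject mean responses rather
    # than uniform random labels.  Random labels make every class fit the
    # grand mean, the random-effect variance absorbs the between-class
    # spread, and the chain can collapse to one class and split only very
    # slowly; binned starts let the sparse prior do the (easy) merging.
    n_bins = min(K, 5)
    order = np.argsort(np.argsort(subj_means, kind="stable"), kind="stable")
    z = (order * n_bins) // n
    b = np.zeros((n, q))

    M = config.n_iter
    store_z = config.store_allocations
    if store_z is None:
        store_z = n <= 1000
    draws = GrowthPosteriorDraws(
        lambda_=np.empty((M, K)),
        theta=np.empty((M, K, p)),
        gamma=np.empty((M, c)),
        Sigma=np.empty((M, K, q, q)),
        resid_var=np.empty(M),
        counts=np.empty((M, K), dtype=np.int64),
        loglik_obs=np.empty(M),
        n_subjects=n,
        allocations=np.empty((M, n), dtype=np.int16) if store_z else None,
    )

    v0 = prior.fixed_effect_var
    S0 = prior.re_scale * np.eye(q)
    total = config.burn_in + M
    eye_p = np.eye(p)

    # All per-class linear algebra below runs through numpy's batched (K, ., .)
    # gufuncs; with one design group this makes the per-iteration cost a
    # handful of vectorized calls instead of O(K) tiny ones.
    for it in range(total):
        counts = np.bincount(z, minlength=K)
        lam = sample_proportions(counts, prior.alpha, rng)

        # --- subject random effects b_i | z, theta, gamma, Sigma, sigma2
        Sigma_inv = np.linalg.inv(Sigma)  # (K, q, q)
        for g in prep.groups:
            Z = g["Z"]
            A = np.linalg.inv(g["ZtZ"][None, :, :] / sigma2 + Sigma_inv)  # (K,q,q)
            LA = np.linalg.cholesky(A)
            zi = z[g["idx"]]
            fixed_own = np.einsum("itp,ip->it", g["X"], theta[zi])
            if c:
                fixed_own = fixed_own + g["W"] @ gamma
            Ztr = (g["Y"] - fixed_own) @ Z / sigma2  # (n_g, q)
            mean = np.einsum("iqr,ir->iq", A[zi], Ztr)
            eps = rng.standard_normal((len(zi), q))
            b[g["idx"]] = mean + np.einsum("iqr,ir->iq", LA[zi], eps)

        # --- class fixed effects theta_j | z, b, gamma, sigma2
        prec = np.tile(eye_p / v0, (K, 1, 1))
        rhs = np.zeros((K, p))
        for g in prep.groups:
            zi = z[g["idx"]]
            resid_t = g["Y"] - b[g["idx"]] @ g["Z"].T
            if c:
                resid_t = resid_t - g["W"] @ gamma
            Xr = np.einsum("itp,it->ip", g["X"], resid_t)
            np.add.at(rhs, zi, Xr / sigma2)
            np.add.at(prec, zi, g["XtX"] / sigma2)
        cov = np.linalg.inv(prec)  # (K, p, p)
        Lc = np.linalg.cholesky(cov)
        mean = np.einsum("kpr,kr->kp", cov, rhs)
        theta = mean + np.einsum("kpr,kr->kp", Lc, rng.standard_normal((K, p)))

        # --- common fixed effects gamma | z, b, theta, sigma2
        if c:
            prec_g = np.eye(c) / v0
            rhs_g = np.zeros(c)
            for g in prep.groups:
                zi = z[g["idx"]]
                resid_c = (
                    g["Y"]
                    - np.einsum("itp,ip->it", g["X"], theta[zi])
                    - b[g["idx"]] @ g["Z"].T
                )
                prec_g = prec_g + g["WtW"] / sigma2
                rhs_g = rhs_g + np.einsum("itc,it->c", g["W"], resid_c) / sigma2
            cov_g = np.linalg.inv(prec_g)
            gamma = _draw_mvn(cov_g @ rhs_g, cov_g, rng)

        # --- random-effect covariances Sigma_j | z, b
        if q == 1:
            ss = np.bincount(z, weights=b[:, 0] ** 2, minlength=K)
            tau = rng.gamma(
                prior.re_prec_shape + counts / 2.0,
                1.0 / (prior.re_prec_rate + ss / 2.0),
            )
            with np.errstate(divide="ignore"):
                var_j = np.where(tau > 0, 1.0 / np.maximum(tau, 1e-300), np.inf)
            Sigma = np.clip(var_j, _VAR_FLOOR, _VAR_CEIL).reshape(K, 1, 1)
        else:
            Sb = np.tile(S0, (K, 1, 1))
            np.add.at(Sb, z, b[:, :, None] * b[:, None, :])
            Sigma = _invwishart_batch(prior.re_df + counts, Sb, rng)
            for j in range(K):
                Sigma[j] = _stabilize_cov(Sigma[j])

        # --- residual precision | z, b, theta, gamma
        rss = 0.0
        for g in prep.groups:
            zi = z[g["idx"]]
            resid_full = (
                g["Y"]
                - np.einsum("itp,ip->it", g["X"], theta[zi])
                - b[g["idx"]] @ g["Z"].T
            )
            if c:
                resid_full = resid_full - g["W"] @ gamma
            rss += float(np.sum(resid_full**2))
        tau = rng.gamma(
            prior.resid_shape + prep.n_rows / 2.0, 1.0 / (prior.resid_rate + rss / 2.0)
        )
        sigma2 = float(np.clip(1.0 / tau, _VAR_FLOOR, _VAR_CEIL))

        # --- subject allocations from the NEW parameters ----------------
        logp = np.empty((n, K))
        for g in prep.groups:
            Z = g["Z"]
            T_g = Z.shape[0]
            fixed = np.einsum("itp,jp->ijt", g["X"], theta)
            if c:
                fixed = fixed + (g["W"] @ gamma)[:, None, :]
            R = g["Y"][:, None, :] - fixed  # (n_g, K, T)
            if marginal_allocation:
                V = np.einsum("tq,kqr,sr->kts", Z, Sigma, Z) + sigma2 * np.eye(T_g)
                Lv = np.linalg.cholesky(V)  # (K, T, T)
                u = np.linalg.solve(Lv, R.transpose(1, 2, 0))  # (K, T, n_g)
                quad = np.einsum("kti,kti->ki", u, u)
                logdet = 2.0 * np.sum(
                    np.log(np.diagonal(Lv, axis1=1, axis2=2)), axis=1
                )
                logp[g["idx"], :] = (
                    -0.5 * (T_g * np.log(2 * np.pi) + logdet[:, None] + quad)
                ).T
            else:
                # conditional on current b (cross-check route)
                r = R - (b[g["idx"]] @ Z.T)[:, None, :]
                logp[g["idx"], :] = -0.5 * (
                    T_g * np.log(2 * np.pi * sigma2)
                    + np.einsum("ikt,ikt->ik", r, r) / sigma2
                )
        with np.errstate(divide="ignore"):
            logp += np.log(np.maximum(lam, 1e-300))[None, :]
        z = np.argmax(logp + rng.gumbel(size=(n, K)), axis=1)

        m = it - config.burn_in
        if m < 0:
            continue
        draws.lambda_[m] = lam
        draws.theta[m] = theta
        draws.gamma[m] = gamma
        draws.Sigma[m] = Sigma
        draws.resid_var[m] = sigma2
        draws.counts[m] = np.bincount(z, minlength=K)
        mx = logp.max(axis=1)
        draws.loglik_obs[m] = float(
            (mx + np.log(np.exp(logp - mx[:, None]).sum(axis=1))).sum()
        )
        if store_z:
            draws.allocations[m] = z

    return draws
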