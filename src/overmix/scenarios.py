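"""Synthetic data generators for the mixture-model selection experiments.

Two families of generative truths are covered:

* univariate location-scale Gaussian mixtures (scenarios ``A1``--``A4``,
  plus the unequal-proportion variant ``A_unequal``), and
* linear growth mixtures, i.e. latent-class linear mixed-effects models
  with class-specific fixed intercept/slope and Gaussian random effects
  (scenarios ``B1``--``B3``).

Scenario objects hold the generative truth only; simulated datasets keep the
true class labels in a separate field that fitting code never receives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "UnivariateScenario",
    "GrowthScenario",
    "UnivariateDataset",
    "LongitudinalDataset",
    "make_scenario",
    "simulate_univariate",
    "simulate_growth",
    "add_tail_outliers",
    "SCENARIO_NAMES",
]

OUTLIER_LABEL = -1


@dataclass(frozen=True)
class UnivariateScenario:
    """Generative truth for a univariate Gaussian mixture.

    Parameters
    ----------
    K_true : number of classes.
    means, sds, proportions : per-class mean, SD and mixing weight.
    n : number of observations per simulated dataset.
    """

    K_true: int
    means: tuple[float, ...]
    sds: tuple[float, ...]
    proportions: tuple[float, ...]
    n: int = 500

    def __post_init__(self) -> None:
        if self.K_true < 1:
            raise ValueError("K_true must be a positive integer")
        if not (len(self.means) == len(self.sds) == len(self.proportions) == self.K_true):
            raise ValueError("means, sds and proportions must each have length K_true")
        p = np.asarray(self.proportions, dtype=float)
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("proportions must be nonnegative and sum to 1")
        if np.any(np.asarray(self.sds, dtype=float) <= 0):
            raise ValueError("sds must be strictly positive")

    @property
    def marginal_mean(self) -> float:
        p = np.asarray(self.proportions)
        return float(p @ np.asarray(self.means))

    @property
    def marginal_variance(self) -> float:
        p = np.asarray(self.proportions)
        mu = np.asarray(self.means)
        s2 = np.asarray(self.sds) ** 2
        mbar = p @ mu
        return float(p @ (s2 + (mu - mbar) ** 2))


@dataclass(frozen=True)
class GrowthScenario:
    """Generative truth for a linear growth mixture.

    Each subject draws a class ``j`` with probability ``proportions[j]``,
    random effects ``b_i ~ N(0, re_cov)`` (intercept only when
    ``random_slope_on`` is False), then responses

        y_it = theta_j0 + b_i0 + (slope_jt + b_i1) * t + eps_it

    where the per-class slope is ``fixed_slopes[j]`` or, when slopes are
    shared across classes, ``common_slope``.
    """

    K_true: int
    fixed_intercepts: tuple[float, ...]
    fixed_slopes: tuple[float, ...] | None
    re_cov: tuple[tuple[float, ...], ...]
    random_slope_on: bool
    common_slope: float | None
    resid_sd: float
    proportions: tuple[float, ...]
    n_subjects: int = 200
    n_obs: int = 6
    time_grid: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0, 4.0, 5.0)

    def __post_init__(self) -> None:
        if self.K_true < 1:
            raise ValueError("K_true must be a positive integer")
        if len(self.fixed_intercepts) != self.K_true:
            raise ValueError("fixed_intercepts must have length K_true")
        if self.fixed_slopes is None and self.common_slope is None:
            raise ValueError("either fixed_slopes or common_slope is required")
        if self.fixed_slopes is not None and len(self.fixed_slopes) != self.K_true:
            raise ValueError("fixed_slopes must have length K_true")
        p = np.asarray(self.proportions, dtype=float)
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("proportions must be nonnegative and sum to 1")
        S = np.asarray(self.re_cov, dtype=float)
        if S.ndim != 2 or S.shape[0] != S.shape[1]:
            raise ValueError("re_cov must be a square matrix")
        if not np.allclose(S, S.T):
            raise ValueError("re_cov must be symmetric")
        if np.min(np.linalg.eigvalsh(S)) < -1e-12:
            raise ValueError("re_cov must be positive semi-definite")
        if self.resid_sd < 0:
            raise ValueError("resid_sd must be nonnegative")
        t = np.asarray(self.time_grid, dtype=float)
        if len(t) != self.n_obs or np.any(np.diff(t) <= 0):
            raise ValueError("time_grid must be strictly increasing with n_obs entries")

    def slope_of_class(self, j: int) -> float:
        if self.fixed_slopes is not None:
            return self.fixed_slopes[j]
        return float(self.common_slope)


@dataclass(frozen=True)
class UnivariateDataset:
    """Simulated univariate sample with the truth kept aside.

    ``true_labels`` uses 0-based class indices; appended outliers carry
    the sentinel label ``OUTLIER_LABEL``.
    """

    values: np.ndarray
    true_labels: np.ndarray

    def __post_init__(self) -> None:
        if len(self.values) != len(self.true_labels):
            raise ValueError("values and true_labels must have equal length")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"y": self.values})

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"label": self.true_labels})


@dataclass(frozen=True)
class LongitudinalDataset:
    """Long-format longitudinal sample with per-subject class truth."""

    frame: pd.DataFrame  # columns: subject_id, time, y [, covariates...]
    true_labels: np.ndarray  # one 0-based label per distinct subject

    def __post_init__(self) -> None:
        counts = self.frame.groupby("subject_id").size()
        if (counts < 1).any():
            raise ValueError("every subject needs at least one row")
        if len(counts) != len(self.true_labels):
            raise ValueError("true_labels must have one entry per subject")

    @property
    def n_subjects(self) -> int:
        return self.frame["subject_id"].nunique()

    def truth_frame(self) -> pd.DataFrame:
        sids = np.sort(self.frame["subject_id"].unique())
        return pd.DataFrame({"subject_id": sids, "label": self.true_labels})


def _diag2(a: float, b: float) -> tuple[tuple[float, ...], ...]:
    return ((a, 0.0), (0.0, b))


_UNIVARIATE: dict[str, UnivariateScenario] = {
    "A1": UnivariateScenario(1, (1.0,), (0.25,), (1.0,), n=500),
    "A2": UnivariateScenario(3, (1.0, 2.0, 3.0), (0.25,) * 3, (1 / 3,) * 3, n=500),
    "A3": UnivariateScenario(3, (1.0, 2.0, 3.0), (0.4,) * 3, (1 / 3,) * 3, n=500),
    "A4": UnivariateScenario(3, (1.0, 2.0, 3.0), (0.7,) * 3, (1 / 3,) * 3, n=500),
    "A_unequal": UnivariateScenario(
        3, (1.0, 2.0, 3.0), (0.25,) * 3, (0.475, 0.475, 0.05), n=500
    ),
}

_GROWTH: dict[str, GrowthScenario] = {
    # Homogeneous population, random intercept and slope.
    "B1": GrowthScenario(
        K_true=1,
        fixed_intercepts=(2.0,),
        fixed_slopes=(-0.2,),
        re_cov=_diag2(0.25**2, 0.025**2),
        random_slope_on=True,
        common_slope=None,
        resid_sd=0.25,
        proportions=(1.0,),
    ),
    # Three classes differing in intercept; shared slope; random intercept only.
    "B2": GrowthScenario(
        K_true=3,
        fixed_intercepts=(1.0, 2.0, 3.0),
        fixed_slopes=None,
        re_cov=((0.25**2,),),
        random_slope_on=False,
        common_slope=-0.2,
        resid_sd=0.25,
        proportions=(1 / 3,) * 3,
    ),
    # Three classes differing in intercept and slope; random intercept + slope.
    "B3": GrowthScenario(
        K_true=3,
        fixed_intercepts=(1.0, 2.0, 3.0),
        fixed_slopes=(-0.1, -0.2, -0.3),
        re_cov=_diag2(0.25**2, 0.025**2),
        random_slope_on=True,
        common_slope=None,
        resid_sd=0.25,
        proportions=(1 / 3,) * 3,
    ),
}

SCENARIO_NAMES = tuple(list(_UNIVARIATE) + list(_GROWTH))


def make_scenario(name: str) -> UnivariateScenario | GrowthScenario:
    """Return the stated parameterization of a named simulation scenario."""
    if name in _UNIVARIATE:
        return _UNIVARIATE[name]
    if name in _GROWTH:
        return _GROWTH[name]
    raise ValueError(
        f"unknown scenario {name!r}; valid names: {', '.join(SCENARIO_NAMES)}"
    )


def simulate_univariate(scenario: UnivariateScenario, seed: int) -> UnivariateDataset:
    """Draw ``scenario.n`` observations from the mixture, recording true labels."""
    if scenario.n <= 0:
        raise ValueError("scenario.n must be positive")
    rng = np.random.default_rng(seed)
    labels = rng.choice(scenario.K_true, size=scenario.n, p=scenario.proportions)
    mu = np.asarray(scenario.means)[labels]
    sd = np.asarray(scenario.sds)[labels]
    values = rng.normal(mu, sd)
    return UnivariateDataset(values=values, true_labels=labels)


def simulate_growth(scenario: GrowthScenario, seed: int) -> LongitudinalDataset:
    """Draw a balanced longitudinal dataset from the growth mixture."""
    rng = np.random.default_rng(seed)
    n, T = scenario.n_subjects, scenario.n_obs
    t = np.asarray(scenario.time_grid)
    labels = rng.choice(scenario.K_true, size=n, p=scenario.proportions)

    S = np.asarray(scenario.re_cov, dtype=float)
    if scenario.random_slope_on:
        b = rng.multivariate_normal(np.zeros(2), S, size=n, method="cholesky")
    else:
        b0 = rng.normal(0.0, np.sqrt(S[0, 0]), size=n)
        b = np.column_stack([b0, np.zeros(n)])

    intercepts = np.asarray(scenario.fixed_intercepts)[labels] + b[:, 0]
    slopes = np.array([scenario.slope_of_class(j) for j in range(scenario.K_true)])[
        labels
    ] + b[:, 1]
    y = intercepts[:, None] + slopes[:, None] * t[None, :]
    y = y + rng.normal(0.0, scenario.resid_sd, size=(n, T))

    frame = pd.DataFrame(
        {
            "subject_id": np.repeat(np.arange(n), T),
            "time": np.tile(t, n),
            "y": y.ravel(),
        }
    )
    return LongitudinalDataset(frame=frame, true_labels=labels)


def add_tail_outliers(
    data: UnivariateDataset, k_per_tail: int, offset: float = 5.0
) -> UnivariateDataset:
    """Append ``k_per_tail`` extreme values at each tail of the sample.

    The appended values sit ``offset`` sample SDs below the minimum and above
    the maximum, so they are unambiguously outside the observed range; their
    labels are the sentinel ``OUTLIER_LABEL``.
    """
    if len(data.values) == 0:
        raise ValueError("cannot add outliers to an empty dataset")
    if k_per_tail < 0:
        raise ValueError("k_per_tail must be nonnegative")
    if k_per_tail == 0:
        return data
    sd = float(np.std(data.values))
    lo = float(np.min(data.values)) - offset * sd
    hi = float(np.max(data.values)) + offset * sd
    extra = np.array([lo] * k_per_tail + [hi] * k_per_tail)
    values = np.concatenate([data.values, extra])
    labels = np.concatenate(
        [data.true_labels, np.full(2 * k_per_tail, OUTLIER_LABEL, dtype=int)]
    )
    return UnivariateDataset(values=values, true_labels=labels)
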