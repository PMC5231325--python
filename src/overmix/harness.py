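"""Factorial simulation driver: scenario x prior x alpha x criterion x psi.

Runs many simulated datasets through a selection pipeline, records the
selected number of classes per dataset, and aggregates success rates
("percentage of datasets whose selected K equals the generative K") together
with the modal selected K -- the summary the comparison tables report.

Per-dataset results are cached as JSON so interrupted experiments resume
bit-identically: dataset seeds derive from the base seed by index, never
from the call sequence.
"""

from __future__ import annotations

import json
import warnings
from collections.abc import Sequence
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .criteria import posterior_K, select_K_by_dic
from .em import em_growth, em_univariate, select_K_bic
from .growth_mcmc import GrowthModelSpec, PriorSpecGrowth, run_gibbs_growth
from .mixture_mcmc import MCMCConfig, PriorSpecUnivariate, run_gibbs_univariate
from .scenarios import (
    GrowthScenario,
    UnivariateScenario,
    make_scenario,
    simulate_growth,
    simulate_univariate,
)

__all__ = [
    "ExperimentConfig",
    "SuccessTable",
    "run_experiment",
    "success_rate",
    "render_table",
    "select_for_dataset",
    "model_spec_for_scenario",
]


@dataclass(frozen=True)
class ExperimentConfig:
    """One experiment: a scenario crossed with selection-method settings.

    ``criteria`` entries are dicts like ``{"criterion": "RM", "alpha": 0.1,
    "psi": 0.02, "mean_prior": "vague", "var_prior": "uniform"}`` or
    ``{"criterion": "BIC", "k_range": [1, 6]}``.
    """

    scenario: str
    criteria: tuple[dict, ...]
    n_datasets: int = 20
    n_iter: int = 10_000
    burn_in: int = 2_000
    K_max: int = 10
    base_seed: int = 1
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.n_datasets < 1:
            raise ValueError("n_datasets must be >= 1")


@dataclass
class SuccessTable:
    """Aggregated selection results keyed by criterion arm."""

    scenario: str
    K_true: int
    rows: dict[str, dict]  # arm label -> {success_pct, modal_K, n_datasets, selected}

    def as_records(self) -> list[dict]:
        return [
            {"arm": k, **{kk: vv for kk, vv in v.items() if kk != "selected"}}
            for k, v in self.rows.items()
        ]


def success_rate(selected: Sequence[int], K_true: int) -> tuple[float, int]:
    """Percentage of runs selecting the generative K, plus the modal selection.

    Mode ties break toward smaller K.
    """
    sel = np.asarray(list(selected), dtype=int)
    if sel.size == 0:
        raise ValueError("selected must be nonempty")
    pct = 100.0 * float(np.mean(sel == K_true))
    ks, counts = np.unique(sel, return_counts=True)
    return pct, int(ks[np.argmax(counts)])


def model_spec_for_scenario(scenario: GrowthScenario) -> GrowthModelSpec:
    """The analysis model matching how a B-scenario was generated."""
    if scenario.random_slope_on:
        return GrowthModelSpec(
            class_specific_terms=("intercept", "time"),
            common_terms=(),
            random_terms=("intercept", "time"),
        )
    return GrowthModelSpec(
        class_specific_terms=("intercept",),
        common_terms=("time",),
        random_terms=("intercept",),
    )


def select_for_dataset(
    scenario: UnivariateScenario | GrowthScenario,
    dataset_seed: int,
    criterion: dict,
    n_iter: int,
    burn_in: int,
    K_max: int,
) -> int:
    """Simulate one dataset and run one selection arm on it; returns K."""
    name = criterion["criterion"].upper()
    if isinstance(scenario, UnivariateScenario):
        data = simulate_univariate(scenario, dataset_seed)
        if name == "RM":
            prior = PriorSpecUnivariate(
                alpha=criterion["alpha"],
                mean_prior=criterion.get("mean_prior", "vague"),
                var_prior=criterion.get("var_prior", "uniform"),
            )
            cfg = MCMCConfig(
                K_max=K_max,
                n_iter=n_iter,
                burn_in=burn_in,
                seed=dataset_seed,
                store_allocations=False,
            )
            draws = run_gibbs_univariate(data, prior, cfg)
            return posterior_K(draws.counts, draws.n_obs, criterion["psi"]).mode
        if name in ("DIC3", "DIC4"):
            prior = PriorSpecUnivariate(
                alpha=criterion["alpha"],
                mean_prior=criterion.get("mean_prior", "vague"),
                var_prior=criterion.get("var_prior", "uniform"),
            )
            cfg = MCMCConfig(
                K_max=K_max, n_iter=n_iter, burn_in=burn_in, seed=dataset_seed
            )
            lo, hi = criterion.get("k_range", (1, 6))
            return select_K_by_dic(
                data, range(lo, hi + 1), prior, cfg, which=name
            ).selected_K
        if name == "BIC":
            lo, hi = criterion.get("k_range", (1, 6))
            return select_K_bic(
                data,
                range(lo, hi + 1),
                lambda d, K: em_univariate(d, K, seed=dataset_seed),
            ).selected_K
        raise ValueError(f"unknown criterion {name!r} for univariate data")

    data = simulate_growth(scenario, dataset_seed)
    model = model_spec_for_scenario(scenario)
    if name == "RM":
        prior = PriorSpecGrowth(alpha=criterion["alpha"])
        cfg = MCMCConfig(
            K_max=K_max,
            n_iter=n_iter,
            burn_in=burn_in,
            seed=dataset_seed,
            store_allocations=False,
        )
        draws = run_gibbs_growth(data, model, prior, cfg)
        return posterior_K(draws.counts, draws.n_subjects, criterion["psi"]).mode
    if name == "BIC":
        lo, hi = criterion.get("k_range", (1, 5))
        return select_K_bic(
            data,
            range(lo, hi + 1),
            lambda d, K: em_growth(d, K, model, seed=dataset_seed),
        ).selected_K
    raise ValueError(f"unknown criterion {name!r} for longitudinal data")


def _arm_label(criterion: dict) -> str:
    name = criterion["criterion"].upper()
    parts = [name]
    if "alpha" in criterion:
        parts.append(f"alpha={criterion['alpha']}")
    if "psi" in criterion:
        parts.append(f"psi={criterion['psi']}")
    return " ".join(parts)


def run_experiment(config: ExperimentConfig, progress: bool = False) -> SuccessTable:
    """Run every (dataset, criterion arm) cell of the experiment.

    Dataset i uses seed ``base_seed + i``, so resuming from the on-disk cache
    (``out_dir``) reproduces an uninterrupted run exactly.  A failing arm is
    recorded as incomplete instead of aborting the whole experiment.
    """
    scenario = make_scenario(config.scenario)
    cache_dir = Path(config.out_dir) if config.out_dir else None
    if cache_dir is not None:
        cache_dir.mkdir(parents=True, exist_ok=True)

    rows: dict[str, dict] = {}
    for criterion in config.criteria:
        label = _arm_label(criterion)
        selected: list[int] = []
        failures = 0
        for i in range(config.n_datasets):
            seed = config.base_seed + i
            cache = (
                cache_dir / f"{config.scenario}_{label.replace(' ', '_')}_{seed}.json"
                if cache_dir
                else None
            )
            if cache is not None and cache.exists():
                selected.append(json.loads(cache.read_text())["selected_K"])
                continue
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", UserWarning)
                    k = select_for_dataset(
                        scenario,
                        seed,
                        criterion,
                        config.n_iter,
                        config.burn_in,
                        config.K_max,
                    )
            except Exception as err:  # arm marked incomplete, experiment goes on
                failures += 1
                warnings.warn(f"arm {label!r} dataset {seed} failed: {err}")
                continue
            selected.append(k)
            if cache is not None:
                cache.write_text(json.dumps({"selected_K": k, "seed": seed}))
            if progress:
                print(f"[{config.scenario}] {label} dataset {i + 1}/{config.n_datasets} -> K={k}")
        if selected:
            pct, modal = success_rate(selected, scenario.K_true)
        else:
            pct, modal = float("nan"), -1
        rows[label] = {
            "success_pct": pct,
            "modal_K": modal,
            "n_datasets": len(selected),
            "failures": failures,
            "selected": selected,
        }
    return SuccessTable(scenario=config.scenario, K_true=scenario.K_true, rows=rows)


def render_table(table: SuccessTable, fmt: str = "markdown") -> str:
    """Render "P%(mode)" cells, one row per criterion arm."""
    if fmt not in ("markdown", "csv"):
        raise ValueError("fmt must be 'markdown' or 'csv'")
    header = ["arm", "result", "n_datasets"]
    lines = []
    if fmt == "markdown":
        lines.append("| " + " | ".join(header) + " |")
        lines.append("|" + "|".join("---" for _ in header) + "|")
    else:
        lines.append(",".join(header))
    for label, row in table.rows.items():
        cell = (
            f"{row['success_pct']:.0f}%({row['modal_K']})"
            if row["n_datasets"]
            else "incomplete"
        )
        vals = [label, cell, str(row["n_datasets"])]
        if fmt == "markdown":
            lines.append("| " + " | ".join(vals) + " |")
        else:
            lines.append(",".join(vals))
    return "\n".join(lines) + "\n"
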