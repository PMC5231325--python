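# overmix

Choosing the number of latent classes in Bayesian finite mixture models by
deliberately overfitting them.

Biostatisticians and epidemiologists who cluster continuous outcomes or
longitudinal trajectories (growth mixture / latent-class mixed models) face
the same awkward question: how many latent classes K?  `overmix` implements
a selection criterion that avoids refitting the model for every candidate
K.  Fit a single overfitted mixture with K_max components and a sparse
symmetric Dirichlet(α) prior on the proportions; when α < d/2 (d = number
of class-specific parameters) the superfluous components empty as the
sample grows, so K can be read off the chain by counting occupied
components per iteration:

```
K^(m) = K_max − Σ_j 1{ N_j^(m) / N ≤ ψ },       selected K = posterior mode of K^(m)
```

with N_j^(m) the units allocated to component j at iteration m and ψ a
small occupancy cut-off (0–0.05).  The package provides:

- **Gibbs samplers** for overfitted univariate Gaussian mixtures (vague or
  hierarchical normal-gamma priors) and for latent-class linear mixed
  models with class-specific fixed effects, class-specific random-effect
  covariances and common covariates,
- **criteria**: the non-empty-class criterion above, plus DIC₃/DIC₄ and
  BIC (via built-in EM fitters) for comparison,
- **scenario generators** replicating the published simulation settings,
  and a factorial **harness** that reproduces the success-rate tables.

## Worked example

```python
from overmix import (
    MCMCConfig, PriorSpecUnivariate, make_scenario, posterior_K,
    run_gibbs_univariate, select_K_bic, simulate_univariate, em_univariate,
)

# three classes at means 1/2/3, SD 0.25, n = 500
data = simulate_univariate(make_scenario("A2"), seed=7)

draws = run_gibbs_univariate(
    data,
    PriorSpecUnivariate(alpha=0.1),          # sparse: below d/2 = 1
    MCMCConfig(K_max=10, n_iter=5000, burn_in=1000, seed=7),
)
pk = posterior_K(draws.counts, draws.n_obs, psi=0.02)
print(pk.counts_by_K, pk.mode)

res = select_K_bic(data, range(1, 7), lambda d, K: em_univariate(d, K, seed=7))
print(res.selected_K, res.values_by_K)
```

Output:

```
{3: 4999, 4: 1} 3
3 {1: 1277.1, 2: 1163.4, 3: 1075.7, 4: 1094.2, 5: 1111.9, 6: 1125.7}
```

Of 5000 retained iterations, 4999 have exactly three components holding
more than 2% of the observations — the posterior mode (and hence the
selected K) is 3, the generative truth.  BIC agrees here: its minimum over
K = 1..6 is at K = 3 (1075.7), with one- and two-class fits several dozen
points worse.  On harder problems the two criteria diverge; that
divergence is what the simulation harness quantifies.

For longitudinal data, `run_gibbs_growth` takes a `GrowthModelSpec` naming
which design columns are class-specific, common, and random; allocation is
subject-level with the random effects integrated out analytically.  A CLI
(`overmix simulate / fit-mixture / fit-growth / select-k / bench`) wraps
these functions; YAML experiment configs for the published comparison
tables live in `experiments/`.

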