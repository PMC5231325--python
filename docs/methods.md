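# Methods

## The problem

Finite mixture models explain population heterogeneity through K latent
classes, but K itself is rarely known.  `overmix` implements a selection
strategy built on the asymptotic behavior of *overfitted* mixtures: fit the
model with K_max components, put a symmetric Dirichlet(α) prior on the
mixing proportions λ, and rely on the result that when α < d/2 — d being
the number of class-specific parameters — the proportions of the
superfluous components converge to zero as the sample grows.  Selection
then reduces to counting, in each MCMC iteration m, the components that are
actually occupied:

    K^(m) = K_max − Σ_j 1{ N_j^(m) / N ≤ ψ },

where N_j^(m) is the number of units allocated to component j and ψ is a
small occupancy cut-off (0, 0.01, 0.02 or 0.05).  The selected K is the
posterior mode of K^(m).  The count is invariant to label permutations, so
no relabeling of the chain is needed.  The competing criteria implemented
for comparison are the mixture-adapted deviance information criteria DIC₃
(observed-data predictive density) and DIC₄ (complete-data likelihood), and
BIC = −2 log f(y|θ̂) + g log n from maximum-likelihood fits.

## Models and priors

**Univariate Gaussian mixture** (`mixture_mcmc`): y_i ~ Σ_j λ_j N(μ_j, σ_j²),
d = 2.  Two prior families:

* vague: μ_j ~ N(0, 1000), σ_j² ~ U(0, 10);
* hierarchical normal-gamma (data-dependent): μ_k | b₀, η ~ N(b₀, ηR²),
  b₀ ~ N(m₀, M₀) with M₀⁻¹ = 10⁻⁷, η ~ Γ(0.5, 0.5);
  1/σ_k² ~ Γ(1.25, 1/(2C₀)), C₀ ~ Γ(0.25, 20/R²), where m₀ and R are the
  sample median and range.  All gammas are shape–rate.

The Gibbs scan is allocations → proportions (Dirichlet conjugate) → means
(normal conjugate) → variances → hyperparameters.  Under the uniform
variance prior the variance full conditional is a truncated inverse-gamma
kernel: the precision is Γ(N_j/2 − 1, SS_j/2) truncated to τ > 1/upper,
drawn by rejection from the untruncated gamma with a grid inverse-CDF
fallback on log σ² for N_j ≤ 2 (where the kernel has an integrable
singularity at zero) and for persistent rejections.  Empty components draw
from their priors, keeping the chain on the full K_max-dimensional space.

**Growth mixture / latent-class linear mixed model** (`growth_mcmc`):

    y_it | class j = x_it'θ_j + w_it'γ + z_it'b_i + ε_it,

with class-specific fixed effects θ_j, common effects γ, subject random
effects b_i ~ N(0, Σ_j) with class-specific covariance, and
ε_it ~ N(0, σ²).  Priors: N(0, 10³) on all fixed effects, Γ(10⁻³, 10⁻³) on
the residual precision, inverse-Wishart(diag(10⁻³), df = 3) on Σ_j (density
∝ |Σ|^−(df+p+1)/2 exp(−tr(SΣ⁻¹)/2); conventions differ across texts, this
one is fixed here), or Γ(10⁻³, 10⁻³) on the random-intercept precision in
the intercept-only model.  d = #class-specific fixed effects + free entries
of Σ_j (5 for random intercept-and-slope models, 2 for the intercept-only
model), and the recommended default α is 0.85·d/2, just under the validity
threshold.

Subject allocation integrates the random effects out analytically —
p(z_i = j) ∝ λ_j MVN(y_i | X_iθ_j + W_iγ, Z_iΣ_jZ_i' + σ²I) — which mixes
far better than conditioning on the current b_i draws; the conditional
route is retained as a cross-check (`marginal_allocation=False`).  This
makes the scheme partially collapsed: b_i is redrawn from its full
conditional immediately after each allocation pass, before any update that
conditions on it.  In Eq.-5 counting, N is the number of subjects (the
exchangeable units), not observation rows.

## Numerical choices

* **Storage pairing.**  The scan is rotated so each retained record pairs
  the stored parameter draw with allocations and log-likelihoods computed
  from those same parameters — required for the complete-data DIC terms.
* **Allocation sampling** uses the Gumbel-max trick on the log-probability
  matrix (exact categorical sampling, no normalization pass).
* **Initialization.**  Univariate: uniform random allocations, means at
  data quantiles, variances at the sample variance.  Growth: subjects are
  binned into min(K_max, 5) quantile groups of their mean response.
  Uniform random subject labels make every class fit the grand mean, let
  the random-effect variance absorb the between-class spread, and the chain
  can collapse to one class from which splitting (the hard Gibbs move) is
  very slow; binned starts leave only merging (the easy move) to the sparse
  prior.  At the study's original chain length (50k iterations) both
  initializations agree; at desk scale the binned start removes a mixing
  artifact, not a posterior feature.
* **Empty-class covariance stabilization.**  The Γ(10⁻³,10⁻³) and
  IW(diag(10⁻³), 3) priors are diffuse enough that empty-class draws
  under/overflow float64 (precision exactly 0); variances are kept in
  [10⁻¹⁰, 10⁶].  Occupied classes never approach these bounds.
* **Sparse Dirichlet draws** go through per-component gammas with a guard
  for total underflow (α = 10⁻⁵ can underflow every component).
* **α ≥ d/2** triggers a warning, not an error: such values are valid
  Bayesian models, just outside the regime where the emptying result holds,
  and the comparison experiments deliberately include them.
* **DIC₄'s inner expectation** E[θ | y, Z] uses conjugate closed forms
  given Z: Dirichlet mean for λ; for each class the variance point value is
  the mean of the (0,10)-truncated inverse-gamma kernel given Z (proper for
  every occupancy, computed on a log-σ² trapezoid grid), and the class mean
  is the conjugate-normal posterior mean with the variance profiled there.
  Empty components take prior means.  The exact estimator behind the
  published DIC₄ values is not fully specified; this reading follows the
  complete-data DIC construction of Celeux and co-authors.
* **Mode ties** (posterior K, success-table modes, DIC/BIC argmin ties)
  always break toward smaller K (parsimony).

## Maximum likelihood and BIC

`em` fits the same models by EM.  Univariate: classical closed-form steps,
variance floor 10⁻⁶·var(y) against the unbounded-likelihood spikes, 10
starts (quantile means plus perturbation) run short (30 iterations) with
the best continued to convergence (relative tolerance 10⁻⁶, max 500
iterations).  Growth: EM over class memberships *and* random effects, the
latter through conditional Gaussian moments, so the subject-level marginal
likelihood increases monotonically (ECM for the θ/γ blocks).  The fitted
frequentist model shares the random-effect covariance across classes, as
the standard latent-class mixed-model packages do by default — with a
class-specific covariance BIC's parameter count (g = 18 at K = 3 for the
random-slope model vs 12 shared) suppresses K = 3 almost everywhere, which
is incompatible with the published mid-range BIC success rates;
`shared_cov=False` restores the class-specific variant.  g counts all free
parameters including K − 1 proportions; the BIC n is the total row count by
default (`bic_n="subjects"` switches to subjects).

## Synthetic data

`scenarios` reproduces the study's generative settings exactly: univariate
three-class mixtures at means (1,2,3) with σ ∈ {0.25, 0.4, 0.7} for high,
moderate and low separation plus a homogeneous and an unequal-proportion
(0.475/0.475/0.05) variant, all n = 500; growth scenarios with 200 subjects
× 6 observations, residual SD 0.25, random-intercept SD 0.25 and (where
present) random-slope SD 0.025.  The time grid is 0..5 (equally spaced; the
source states only "6 observations per subject").  Tail outliers are placed
5 sample SDs beyond the observed range (magnitude unstated in the source;
the choice is configurable).  Labels live in a separate truth container
that fitting code never receives.

The generator emulates the stated stochastic structure and nothing else: no
missing data, no non-Gaussian components, no informative dropout.  Green
tests therefore establish that the samplers and criteria behave as
published *under the stated models*, not robustness to real-data
violations of them.

## Known limitations

* Split moves are not implemented; very short chains started from a merged
  state can under-count classes (mitigated, not eliminated, by the binned
  initialization).
* The hierarchical normal-gamma prior is univariate-only.
* DIC selection refits a chain per candidate K and is the slowest path.
* The donor-hemoglobin application (4 trajectory classes) needs the
  external longitudinal dataset and a 50k-iteration run; it is exercised
  only by an optional integration test when the data file is supplied.
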