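# Methods

## Model

`mortmap` implements the standard spatio-temporal extension of the BYM
convolution model for areal counts.  For area i = 1..N and period
t = 1..T,

    O_it ~ Poisson(E_it * rho_it)
    log rho_it = alpha + s_i + u_i + sum_k beta_k x_ik + (gamma + delta_i) * time_t

The observed quantity is a mortality ratio per 100,000 live births treated
directly as a Poisson count.  Expected counts E_it are all 1 by default
(the ratio is already standardized to a common denominator); the
alternative `internal` mode computes E_it = P_it * (sum_i O_it / sum_i P_it)
within each period, which preserves period totals exactly.  Non-integer
observed values are rejected rather than rounded, forcing any
preprocessing to be explicit.

### Priors

* `s` (structured spatial) and `delta` (area-specific trend deviation)
  carry intrinsic CAR priors with unit adjacency weights:
  log p(x) = ((n - c)/2) log tau - (tau/2) sum_{i~j} (x_i - x_j)^2, where c
  counts the connected components of the contiguity graph.  The intrinsic
  prior is improper; identifiability is restored by sum-to-zero centering
  per connected component.  We use the intrinsic form rather than a proper
  CAR with an autocorrelation parameter: it is the canonical
  disease-mapping formulation and introduces no extra parameter.
* Islands (areas without neighbours) have their spatial effects fixed at
  zero; their variation is carried entirely by `u`.
* `u_i ~ Normal(0, 1/tau_u)` iid.
* Fixed effects `alpha, gamma, beta_k ~ Normal(0, 1000^2)` (vague, proper).
* Precisions `tau_s, tau_u, tau_delta ~ Gamma(shape 1, rate 0.0005)`, a
  widespread vague disease-mapping default (prior mean 2000).  All
  hyperparameters are exposed through `Hyperparams`.

### Time coding and covariates

Time is coded 1..T and centered by default, which decorrelates `alpha` and
`gamma` and makes `gamma` the trend at the panel midpoint.  Covariates are
area-level and time-constant (one cross-sectional survey joined to several
ratio periods) and are z-scaled by default: coefficient magnitudes around
±0.1-1 on percentage-scale inputs are only interpretable on a standardized
scale.  Model 2 bundles six maternal-health covariates, model 3 eleven
health-system covariates; arbitrary custom sets are supported.

## Inference

Posterior sampling is Metropolis-within-Gibbs:

* scalar adaptive random-walk Metropolis for `alpha`, `gamma`, each
  `beta_k`;
* blocked single-site random-walk Metropolis for `s`, `u`, `delta`,
  vectorised over greedy graph-colouring classes (no two sites updated
  simultaneously share an edge, so the single-site acceptance ratios are
  exact).  The ICAR term in the acceptance ratio is the full-conditional
  pairwise-difference form.  A random-walk proposal was chosen over an
  independence proposal drawn from the prior full conditional because the
  latter mixes arbitrarily badly when the likelihood is much tighter than
  the prior — precisely the regime of count panels with hundreds of events
  per cell;
* conjugate Gibbs draws for the precisions, with the ICAR shape using the
  rank (n - c) of the graph Laplacian;
* proposal scales adapt by Robbins-Monro toward 0.44 acceptance during
  burn-in only and are frozen afterwards, so the retained draws come from
  a fixed-kernel chain.  Acceptance rates outside [0.05, 0.95] after
  adaptation are recorded as warnings in the draw metadata.

After each sweep `s` and `delta` are re-centered to sum to zero per
connected component, with the removed mean absorbed into `alpha`
(respectively `gamma`).  On a connected graph this transformation leaves
the linear predictor exactly invariant and both the ICAR prior and the
(nearly flat) fixed-effect priors unchanged; on multi-component graphs the
compensation is the size-weighted overall mean and the move is approximate
(the shipped lattice and contiguity graphs are connected).

The engine replaces the nested Laplace approximation commonly used for
these models: the model, not the approximation method, is the scientific
content, and posterior means from the two engines can differ at the second
decimal.  Multi-chain runs derive per-chain seeds from one root seed and
concatenate post-burn-in draws; identical seeds give bitwise-identical
output.

### Derived quantities

* Spatial relative risk: `exp(posterior mean of s_i)` — deliberately the
  exponential of the mean, not the mean of exponentials, matching the
  convention of the published analyses this mirrors; likewise the `rr`
  column of the posterior summary is `exp(mean)`.
* Exceedance probability: fraction of retained draws with `s_i > 0`;
  hot-spot label for `p > 0.5` strictly, ties labelled cold.
* Trend direction: "rising" for strictly positive posterior mean of
  `delta_i`, "declining" otherwise (the boundary case is fixed by
  convention and documented here).
* DIC conditions on the full latent field: D(theta) = -2 log L including
  the log O! terms (so deviances are absolute and comparable across
  models), Dbar averaged over draws, pD = Dbar - D(posterior means of all
  of alpha, gamma, beta, s, u, delta), DIC = Dbar + pD.

## Synthetic-data generator

`simulate_panel` draws from the forward model: `s` and `delta` from the
ICAR distribution (eigen-decomposition of the component Laplacian,
pseudo-inverse covariance on the positive eigenspace, then centering), `u`
iid normal, counts Poisson.  Defaults emulate a state-level
mortality-ratio panel: E = 1, alpha = log 80 so area means span roughly
20-250, a common declining trend gamma = -0.12 per period (the magnitude
reported by published national analyses), tau_s = tau_delta = 10,
tau_u = 100.  The precisions are fixture choices — the published analyses
report none.  Covariates are standardized Gaussians, optionally correlated
with the standardized spatial surface.

What the generator does *not* emulate: survey sampling error in the
ratios, rolling-window overlap between periods, time-varying covariates,
and district-level geography.  Passing recovery tests therefore shows the
inference machinery is correct under the model's own assumptions, not that
the model is adequate for any particular real panel.

## Validation studies

The acceptance suite (and `scripts/acceptance.py`) validates the pipeline
at three levels.

* **Exact oracles.**  The relative-risk transform round-trips the embedded
  published coefficient table; the ICAR full conditionals reconstruct the
  joint kernel (Brook's lemma) on every graph with <= 4 nodes; the Poisson
  log-likelihood matches an independent log-pmf oracle; OLS trend fits
  match a hand-rolled normal-equations solver to 1e-10.
* **Small-instance posterior oracle.**  A 2-area, 2-period model-1
  posterior with fixed precisions is integrated on a dense 6-dimensional
  grid (axes centred by a Laplace fit, 17 points over ±5 posterior sd);
  MCMC marginal means agree within 0.02.
* **Simulation studies** on the 19-state contiguity graph, T = 5:
  - *Recovery* (20 panels, alpha = 2.3, gamma = -0.12, tau_s = tau_delta
    = 10, tau_u = 100, E = 100): 95% credible intervals cover the true
    trend in >= 16/20 fits and the sign of every sizeable trend deviation
    (|delta_i| >= 0.05) is recovered in >= 90% of area-replicates.
  - *Hot-spot detection* (10 panels): a geographically contiguous block of
    nine states elevated at s = +0.5 (remainder at -0.5, one neutral) is
    flagged hot (p > 0.5) in >= 90% of area-replicates.  The block is
    contiguous by design: the ICAR/iid decomposition attributes a
    spatially *incoherent* ±0.5 pattern to the unstructured component, so
    exceedance on `s` would sit near 0.5 by construction — a spatial hot
    spot is a spatially structured phenomenon.
  - *Model comparison* (20 panels): DIC prefers the model containing a
    real covariate effect (beta = 0.5, covariate correlated 0.5 with the
    spatial surface, area means ~30) in >= 18/20 panels.  These conditions
    were fixed by a power analysis of the expected DIC difference against
    its Monte-Carlo noise: at much higher counts a free BYM field absorbs
    an area-level covariate almost without DIC penalty and the comparison
    has no power; at area means ~30 the expected difference is about -2
    with noise near 1.
  Replicate fits use 1000-2000 retained draws each (3000-12000 sweeps,
  single chain) so the full suite completes in a few minutes on one CPU;
  these sizes are study-design choices balancing Monte-Carlo error against
  replicate count.

## Numerical notes and limitations

* The linear predictor is clipped at ±700 before exponentiation (clips are
  counted); the cached Poisson means are refreshed from scratch
  periodically to prevent incremental drift.
* Posterior summaries use equal-tailed empirical 2.5/97.5 percentiles and
  require at least 100 retained draws.
* `zscale_columns` uses the sample (n-1) standard deviation and maps
  constant columns to zeros; per-area OLS trend confidence intervals use
  the t distribution with T-2 degrees of freedom (normal intervals are
  badly anti-conservative at T = 5), and r² of a constant response is
  defined as 0.
* The heatmap orientation (standardize within time columns vs within area
  rows) is a user flag with `by_column` as default; the two are transposes
  of one another.
* Only the binary hot/cold exceedance rule is implemented; no scan
  statistics or intermediate probability bands.
* WAIC/LOO, proper (Leroux) CAR models, nonlinear temporal effects and
  time-varying covariates are out of scope.
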