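# mortmap

Bayesian spatio-temporal disease mapping for areal mortality-ratio panels.

`mortmap` fits Poisson areal-count models with conditionally autoregressive
(CAR) spatial structure to short panels of the kind produced by national
sample-registration systems: N areas (states) observed over T periods, with
an observed maternal mortality ratio per area and period treated as a
Poisson count, optional area-level covariates (antenatal care coverage,
skilled birth attendance, health-system indices, ...), and a contiguity
graph linking neighbouring areas.  It answers the questions such panels are
collected for: which areas carry excess spatial risk, where is risk rising
against the national trend, and whether maternal-health or health-system
covariates explain the variation.

## Model

Observed counts follow

```
O_it ~ Poisson(E_it * rho_it),   i = 1..N areas,  t = 1..T periods
log rho_it = alpha + s_i + u_i + sum_k beta_k x_ik + (gamma + delta_i) * time_t
```

* `alpha` — overall log-risk level;
* `s_i` — spatially structured effect, intrinsic CAR (ICAR) prior on the
  contiguity graph with sum-to-zero constraint (BYM decomposition);
* `u_i` — unstructured iid Normal(0, 1/tau_u) effect;
* `gamma` — common linear time trend; `delta_i` — area-specific deviation
  from it (also ICAR, sum-to-zero), so `delta_i > 0` marks locally rising
  risk;
* `beta` — covariate effects on standardized area-level covariates
  (model 1: none; model 2: six maternal-health factors; model 3: eleven
  health-system factors);
* Gamma(1, 0.0005) hyperpriors on the precisions, Normal(0, 1000^2) on the
  fixed effects; `E_it` is 1 when the observed quantity is already a
  standardized ratio, or internally standardized from denominators.

Inference is Metropolis-within-Gibbs MCMC (adaptive random-walk updates,
conjugate Gibbs for the precisions).  Post-inference the package computes
the spatial relative risk `exp(mean s_i)`, the exceedance probability
`P(rho_i > 1 | data)` with the hot-spot rule `p > 0.5`, per-area trend
summaries, and DIC for model comparison.  A descriptive layer provides
per-area OLS trend fits with 95% confidence intervals and column-
standardised heatmap matrices.

## Worked example

```python
import numpy as np
from mortmap import (CARSpatioTemporalPoisson, ModelSpec, make_srs_graph,
                     simulate_panel)

graph = make_srs_graph()                      # 19-state contiguity graph
panel, truth = simulate_panel(
    graph, truth=dict(alpha=2.3, gamma=-0.12, tau_s=10.0, tau_u=100.0,
                      tau_delta=10.0),
    T=5, expected=100.0, seed=42,
)
model = CARSpatioTemporalPoisson(panel, graph, ModelSpec.model1(), expected=100.0)
res = model.fit(iters=6000, burnin=3000, thin=3, chains=2, seed=7)

print(res.summary().loc[["alpha", "gamma", "tau_s"]].round(4))
print(res.risk_report().sort_values("exceed_prob", ascending=False).head())
stats = res.dic()
print(f"DIC = {stats.dic:.1f}  (Dbar = {stats.dbar:.1f}, pD = {stats.p_d:.1f})")
```

prints

```
              mean      sd    q2.5    q97.5       rr
parameter
alpha       2.3238  0.0068  2.3110   2.3382  10.2149
gamma      -0.1236  0.0024 -0.1282  -0.1189   0.8837
tau_s      10.0353  3.3709  4.7561  17.9640      NaN

       area_id  spatial_rr  exceed_prob label  delta_mean  delta_lo  delta_hi
Andhra Pradesh       1.171        1.000   hot      -0.113    -0.132    -0.096
   Uttarakhand       1.148        1.000   hot       0.379     0.361     0.397
 Uttar Pradesh       1.169        1.000   hot       0.081     0.064     0.098
        Punjab       2.054        1.000   hot       0.203     0.189     0.216
        Odisha       1.073        0.988   hot      -0.025    -0.042    -0.007

DIC = 963.1  (Dbar = 925.8, pD = 37.3)
```

The panel was simulated with a common trend of -0.12 per period; the
posterior mean recovers it as -0.1236 with a 95% credible interval
(-0.128, -0.119).  The relative-risk column is `exp(posterior mean)`; the
risk report labels areas "hot" whenever the posterior probability of a
spatial relative risk above 1 exceeds 0.5.

The same pipeline runs from the shell:

```bash
mortmap simulate --graph srs --seed 1 --outdir data/
mortmap fit --counts data/counts.csv --graph data/graph.txt \
            --model 1 --seed 2 --outdir out/
mortmap risk --draws out/draws.csv --out out/risk.csv
mortmap trends --counts data/counts.csv --out out/trends.csv
```

or end-to-end from a YAML config with `mortmap run --config cfg.yaml`.

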