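"""Metropolis-within-Gibbs posterior sampling for the CAR spatio-temporal model.

Update scheme per sweep:

* fixed effects alpha, gamma, beta_k: scalar adaptive random-walk Metropolis
  with vague Normal(0, 1000^2) priors;
* latent fields s (ICAR), u (iid), delta (ICAR): blocked single-site
  random-walk Metropolis, vectorised over graph-colouring classes so that
  no two sites updated together share an edge; the ICAR contribution to the
  acceptance ratio is the full-conditional pairwise-difference form;
* s and delta are re-centered to sum zero per connected component after the
  field updates, with the removed mean absorbed into alpha (resp. gamma) --
  on a connected graph this leaves the linear predictor exactly invariant;
* precisions tau_s, tau_u, tau_delta: conjugate Gamma Gibbs draws.

Proposal scales adapt by Robbins-Monro toward 0.44 acceptance during
burn-in and are frozen afterwards, preserving detailed balance for the
retained draws.  All randomness flows from a single integer seed; chains
use seeds spawned from it and their post-burn-in draws are concatenated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .design import ModelSpec, build_design, encode_time, linear_predictor, poisson_loglik
from .panel import AdjacencyGraph, ArealPanel

__all__ = [
    "PosteriorDraws",
    "ModelFitStats",
    "run_mcmc",
    "summarize_draws",
    "rr_transform",
    "compute_dic",
    "save_draws",
    "load_draws",
]

_PRIOR_VAR = 1000.0**2  # fixed-effect prior variance
_TARGET = 0.44


@dataclass
class PosteriorDraws:
    """Retained posterior draws (chains concatenated after burn-in)."""

    alpha: np.ndarray
    gamma: np.ndarray
    beta: np.ndarray
    s: np.ndarray
    u: np.ndarray
    delta: np.ndarray
    tau_s: np.ndarray
    tau_u: np.ndarray
    tau_delta: np.ndarray
    covariate_names: list = field(default_factory=list)
    area_ids: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        M = len(self.alpha)
        for name in ("gamma", "beta", "s", "u", "delta", "tau_s", "tau_u", "tau_delta"):
            if len(getattr(self, name)) != M:
                raise ValueError(f"draw array {name} does not match length {M}")

    @property
    def n_draws(self) -> int:
        return len(self.alpha)

    @property
    def n_areas(self) -> int:
        return self.s.shape[1]


@dataclass
class ModelFitStats:
    """Deviance summaries: DIC = Dbar + pD with pD = Dbar - D(theta_bar)."""

    dbar: float
    d_at_mean: float
    p_d: float
    dic: float

    def to_dict(self):
        return {"dbar": self.dbar, "d_at_mean": self.d_at_mean, "p_d": self.p_d, "dic": self.dic}


def rr_transform(coef: float) -> float:
    """Relative risk exp(coef), reported at 6 significant digits."""
    coef = float(coef)
    if not np.isfinite(coef):
        raise ValueError("coefficient must be finite")
    return float(f"{np.exp(coef):.6g}")


# ---------------------------------------------------------------------------
# chain internals
# ---------------------------------------------------------------------------

def _adapt(scale, acc, sweep):
    step = (sweep + 10.0) ** -0.6
    return np.clip(scale * np.exp(step * (acc - _TARGET)), 1e-5, 50.0)


class _AccTracker:
    def __init__(self):
        self.hits = 0.0
        self.trials = 0.0

    def add(self, acc):
        self.hits += float(np.sum(acc))
        self.trials += float(np.size(acc))

    @property
    def rate(self):
        return self.hits / self.trials if self.trials else float("nan")


def _run_chain(O, E, t, X, graph, spec, iters, burnin, thin, rng,
               fix_precisions, use_likelihood):
    N, T = O.shape
    K = X.shape[1]
    hyper = spec.hyper
    logE = np.log(E)

    rowO = O.sum(axis=1).astype(float)
    totO = rowO.sum()
    rowOt = (O * t[None, :]).sum(axis=1)
    totOt = rowOt.sum()

    deg = graph.degrees.astype(float)
    island = deg == 0
    use_s = spec.spatial
    use_u = spec.unstructured
    use_g = spec.trend
    use_d = spec.interaction
    if (use_s or use_d) and graph.n_edges == 0:
        raise ValueError("spatial/interaction CAR effects need a graph with at least one edge")
    colors = [c[~island[c]] for c in graph.color_classes()]
    colors = [c for c in colors if len(c)]
    comps = [c for c in graph.components if len(c) >= 2]
    icar_rank = sum(len(c) - 1 for c in comps)
    single_comp = len(comps) == 1 and not island.any()
    ea, eb = (graph.edges[:, 0], graph.edges[:, 1]) if graph.n_edges else (None, None)

    # state
    alpha = float(np.log((totO + 0.5) / E.sum()))
    gamma = 0.0
    beta = np.zeros(K)
    s = np.zeros(N)
    u = np.zeros(N)
    delta = np.zeros(N)
    if fix_precisions:
        tau_s = float(fix_precisions.get("tau_s", 10.0))
        tau_u = float(fix_precisions.get("tau_u", 100.0))
        tau_d = float(fix_precisions.get("tau_delta", 10.0))
    else:
        tau_s, tau_u, tau_d = 10.0, 100.0, 10.0

    def full_eta():
        return linear_predictor(alpha, s, u, beta if K else None, X if K else None,
                                gamma, delta, t)

    eta = full_eta()
    mu = E * np.exp(np.clip(eta, -700, 700))
    if use_likelihood and not np.isfinite(poisson_loglik(O, E, eta)):
        raise ValueError("non-finite likelihood at initialisation")

    sc = {
        "alpha": 0.1,
        "gamma": 0.1,
        "beta": np.full(K, 0.1),
        "s": np.full(N, 0.1),
        "u": np.full(N, 0.1),
        "delta": np.full(N, 0.05),
    }
    acc = {k: _AccTracker() for k in ("alpha", "gamma", "beta", "s", "u", "delta")}

    n_keep = (iters - burnin + thin - 1) // thin
    out = {
        "alpha": np.empty(n_keep),
        "gamma": np.empty(n_keep),
        "beta": np.empty((n_keep, K)),
        "s": np.empty((n_keep, N)),
        "u": np.empty((n_keep, N)),
        "delta": np.empty((n_keep, N)),
        "tau_s": np.empty(n_keep),
        "tau_u": np.empty(n_keep),
        "tau_delta": np.empty(n_keep),
    }
    kept = 0

    for sweep in range(iters):
        adapting = sweep < burnin
        post = sweep >= burnin

        if not use_likelihood:
            # prior-only mode: exact Gibbs draws from the conditional priors
            alpha = rng.normal(0.0, np.sqrt(_PRIOR_VAR))
            gamma = rng.normal(0.0, np.sqrt(_PRIOR_VAR)) if use_g else 0.0
            if K:
                beta = rng.normal(0.0, np.sqrt(_PRIOR_VAR), size=K)
            if use_u:
                u = rng.standard_normal(N) / np.sqrt(tau_u)
            if use_s:
                for A in colors:
                    nb = graph.neighbor_sums(s)[A]
                    s[A] = rng.normal(nb / deg[A], 1.0 / np.sqrt(tau_s * deg[A]))
            if use_d:
                for A in colors:
                    nb = graph.neighbor_sums(delta)[A]
                    delta[A] = rng.normal(nb / deg[A], 1.0 / np.sqrt(tau_d * deg[A]))
        else:
            # alpha
            d = rng.normal(0.0, sc["alpha"])
            dll = d * totO - mu.sum() * np.expm1(d)
            dlp = -(2 * alpha * d + d * d) / (2 * _PRIOR_VAR)
            ok = np.log(rng.uniform()) < dll + dlp
            if ok:
                alpha += d
                eta += d
                mu *= np.exp(d)
            if post:
                acc["alpha"].add(ok)
            if adapting:
                sc["alpha"] = _adapt(sc["alpha"], float(ok), sweep)

            # gamma
            if use_g:
                d = rng.normal(0.0, sc["gamma"])
                f = np.expm1(d * t)
                dll = d * totOt - mu.sum(axis=0) @ f
                dlp = -(2 * gamma * d + d * d) / (2 * _PRIOR_VAR)
                ok = np.log(rng.uniform()) < dll + dlp
                if ok:
                    gamma += d
                    eta += d * t[None, :]
                    mu *= np.exp(d * t)[None, :]
                if post:
                    acc["gamma"].add(ok)
                if adapting:
                    sc["gamma"] = _adapt(sc["gamma"], float(ok), sweep)

            # beta
            for k in range(K):
                x = X[:, k]
                d = rng.normal(0.0, sc["beta"][k])
                f = np.expm1(d * x)
                dll = d * (x @ rowO) - mu.sum(axis=1) @ f
                dlp = -(2 * beta[k] * d + d * d) / (2 * _PRIOR_VAR)
                ok = np.log(rng.uniform()) < dll + dlp
                if ok:
                    beta[k] += d
                    eta += (d * x)[:, None]
                    mu *= np.exp(d * x)[:, None]
                if post:
                    acc["beta"].add(ok)
                if adapting:
                    sc["beta"][k] = _adapt(sc["beta"][k], float(ok), sweep)

            # s field
            if use_s:
                for A in colors:
                    d = rng.standard_normal(len(A)) * sc["s"][A]
                    dll = d * rowO[A] - mu[A].sum(axis=1) * np.expm1(d)
                    nb = graph.neighbor_sums(s)[A]
                    dlp = -0.5 * tau_s * (deg[A] * d * d + 2 * d * (deg[A] * s[A] - nb))
                    ok = np.log(rng.uniform(size=len(A))) < dll + dlp
                    if ok.any():
                        idx, da = A[ok], d[ok]
                        s[idx] += da
                        eta[idx] += da[:, None]
                        mu[idx] *= np.exp(da)[:, None]
                    if post:
                        acc["s"].add(ok)
                    if adapting:
                        sc["s"][A] = _adapt(sc["s"][A], ok.astype(float), sweep)

            # u field (all sites conditionally independent)
            if use_u:
                d = rng.standard_normal(N) * sc["u"]
                dll = d * rowO - mu.sum(axis=1) * np.expm1(d)
                dlp = -0.5 * tau_u * (2 * u * d + d * d)
                ok = np.log(rng.uniform(size=N)) < dll + dlp
                if ok.any():
                    da = d[ok]
                    u[ok] += da
                    eta[ok] += da[:, None]
                    mu[ok] *= np.exp(da)[:, None]
                if post:
                    acc["u"].add(ok)
                if adapting:
                    sc["u"] = _adapt(sc["u"], ok.astype(float), sweep)

            # delta field
            if use_d:
                for A in colors:
                    d = rng.standard_normal(len(A)) * sc["delta"][A]
                    f = np.expm1(np.outer(d, t))
                    dll = d * rowOt[A] - (mu[A] * f).sum(axis=1)
                    nb = graph.neighbor_sums(delta)[A]
                    dlp = -0.5 * tau_d * (deg[A] * d * d + 2 * d * (deg[A] * delta[A] - nb))
                    ok = np.log(rng.uniform(size=len(A))) < dll + dlp
                    if ok.any():
                        idx, da = A[ok], d[ok]
                        delta[idx] += da
                        eta[idx] += np.outer(da, t)
                        mu[idx] *= np.exp(np.outer(da, t))
                    if post:
                        acc["delta"].add(ok)
                    if adapting:
                        sc["delta"][A] = _adapt(sc["delta"][A], ok.astype(float), sweep)

        # re-center s and delta per component; absorb the shift into alpha/gamma
        if use_s:
            shift = 0.0
            for comp in comps:
                m = s[comp].mean()
                s[comp] -= m
                shift += len(comp) * m
            alpha += shift / N
        if use_d:
            shift = 0.0
            for comp in comps:
                m = delta[comp].mean()
                delta[comp] -= m
                shift += len(comp) * m
            gamma += shift / N
        if use_likelihood and (use_s or use_d):
            if not single_comp or sweep % 200 == 199:
                eta = full_eta()
                mu = E * np.exp(np.clip(eta, -700, 700))

        # precisions
        if not fix_precisions:
            if use_s:
                pw = float(((s[ea] - s[eb]) ** 2).sum())
                tau_s = rng.gamma(hyper.a_s + 0.5 * icar_rank, 1.0 / (hyper.b_s + 0.5 * pw))
            if use_u:
                tau_u = rng.gamma(hyper.a_u + 0.5 * N, 1.0 / (hyper.b_u + 0.5 * float(u @ u)))
            if use_d:
                pw = float(((delta[ea] - delta[eb]) ** 2).sum())
                tau_d = rng.gamma(hyper.a_d + 0.5 * icar_rank, 1.0 / (hyper.b_d + 0.5 * pw))

        if post and (sweep - burnin) % thin == 0:
            out["alpha"][kept] = alpha
            out["gamma"][kept] = gamma
            out["beta"][kept] = beta
            out["s"][kept] = s
            out["u"][kept] = u
            out["delta"][kept] = delta
            out["tau_s"][kept] = tau_s
            out["tau_u"][kept] = tau_u
            out["tau_delta"][kept] = tau_d
            kept += 1

    for key in out:
        out[key] = out[key][:kept]
    rates = {k: v.rate for k, v in acc.items() if v.trials}
    return out, rates


def run_mcmc(
    panel: ArealPanel,
    graph: AdjacencyGraph,
    spec: ModelSpec,
    E=None,
    iters: int = 20000,
    burnin: int = 10000,
    thin: int = 5,
    chains: int = 4,
    seed: int | None = None,
    fix_precisions=None,
    use_likelihood: bool = True,
) -> PosteriorDraws:
    """Sample the posterior of the spatio-temporal model.

    ``E`` defaults to the panel's stored expected counts, else all ones.
    ``fix_precisions`` (dict with tau_s/tau_u/tau_delta) holds the
    precisions at fixed values instead of sampling them -- used by
    small-instance validation.  ``use_likelihood=False`` samples the prior
    only (a correctness diagnostic).
    """
    if seed is None:
        raise ValueError("a seed is required for reproducible sampling")
    if iters <= burnin:
        raise ValueError("iters must exceed burnin")
    if thin < 1 or chains < 1:
        raise ValueError("thin and chains must be >= 1")
    if graph.n != panel.n_areas:
        raise ValueError("graph size does not match the panel")

    if E is None:
        E = panel.E if panel.E is not None else np.ones_like(panel.O, dtype=float)
    E = np.asarray(E, dtype=float)
    if E.ndim == 0:
        E = np.full_like(panel.O, float(E), dtype=float)

    X, names = build_design(panel, spec)
    t = encode_time(panel.n_times, spec.time_coding)

    root = np.random.SeedSequence(seed)
    children = root.spawn(chains)
    chains_out, chain_rates = [], []
    for ss in children:
        rng = np.random.Generator(np.random.PCG64(ss))
        draws, rates = _run_chain(
            panel.O, E, t, X, graph, spec, iters, burnin, thin, rng,
            fix_precisions, use_likelihood,
        )
        chains_out.append(draws)
        chain_rates.append(rates)

    cat = {k: np.concatenate([c[k] for c in chains_out], axis=0) for k in chains_out[0]}
    warn = []
    for ci, rates in enumerate(chain_rates):
        for block, r in rates.items():
            if np.isfinite(r) and not (0.05 <= r <= 0.95):
                warn.append(
                    f"chain {ci}: acceptance rate {r:.3f} for {block} outside [0.05, 0.95]"
                )
    meta = {
        "seed": seed,
        "chains": chains,
        "iters": iters,
        "burnin": burnin,
        "thin": thin,
        "acceptance": chain_rates,
        "warnings": warn,
        "model_id": spec.model_id,
    }
    return PosteriorDraws(
        alpha=cat["alpha"],
        gamma=cat["gamma"],
        beta=cat["beta"],
        s=cat["s"],
        u=cat["u"],
        delta=cat["delta"],
        tau_s=cat["tau_s"],
        tau_u=cat["tau_u"],
        tau_delta=cat["tau_delta"],
        covariate_names=list(names),
        area_ids=list(panel.area_ids),
        meta=meta,
    )


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def _scalar_rows(draws: PosteriorDraws):
    yield "alpha", draws.alpha, True
    yield "gamma", draws.gamma, True
    for k, name in enumerate(draws.covariate_names):
        yield f"beta:{name}", draws.beta[:, k], True
    ids = draws.area_ids or list(range(1, draws.n_areas + 1))
    for i, a in enumerate(ids):
        yield f"s:{a}", draws.s[:, i], False
    for i, a in enumerate(ids):
        yield f"u:{a}", draws.u[:, i], False
    for i, a in enumerate(ids):
        yield f"delta:{a}", draws.delta[:, i], False
    yield "tau_s", draws.tau_s, False
    yield "tau_u", draws.tau_u, False
    yield "tau_delta", draws.tau_delta, False


def summarize_draws(draws: PosteriorDraws) -> pd.DataFrame:
    """Posterior mean, sd and equal-tailed 95% interval per scalar parameter.

    The ``rr`` column is exp(posterior mean) for the regression parameters
    (alpha, gamma, beta) -- deliberately *not* mean(exp(draws)).
    """
    if draws.n_draws < 100:
        raise ValueError("need at least 100 retained draws to summarise")
    rows = []
    for name, v, is_reg in _scalar_rows(draws):
        mean = float(v.mean())
        rows.append(
            {
                "parameter": name,
                "mean": mean,
                "sd": float(v.std(ddof=1)),
                "q2.5": float(np.percentile(v, 2.5)),
                "q97.5": float(np.percentile(v, 97.5)),
                "rr": rr_transform(mean) if is_reg else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("parameter")


def compute_dic(draws: PosteriorDraws, panel: ArealPanel, E, spec: ModelSpec) -> ModelFitStats:
    """DIC conditioned on the full latent field.

    D(theta) = -2 log L; Dbar averages D over draws; D(theta_bar) plugs in
    the posterior means of alpha, gamma, beta, s, u, delta.
    """
    if draws.n_draws == 0:
        raise ValueError("no draws")
    O = panel.O.astype(float)
    E = np.asarray(E, dtype=float)
    if E.ndim == 0:
        E = np.full_like(O, float(E))
    X, _ = build_design(panel, spec)
    t = encode_time(panel.n_times, spec.time_coding)

    xb = draws.beta @ X.T if draws.beta.shape[1] else np.zeros((draws.n_draws, panel.n_areas))
    level = draws.alpha[:, None] + draws.s + draws.u + xb            # (M, N)
    slope = draws.gamma[:, None] + draws.delta                        # (M, N)
    eta = level[:, :, None] + slope[:, :, None] * t[None, None, :]    # (M, N, T)
    eta = np.clip(eta, -700, 700)
    const = gammaln(O + 1.0)
    ll = (O[None] * (np.log(E)[None] + eta) - E[None] * np.exp(eta) - const[None]).sum(
        axis=(1, 2)
    )
    dbar = float(np.mean(-2.0 * ll))

    eta_bar = np.clip(
        (level.mean(axis=0))[:, None] + (slope.mean(axis=0))[:, None] * t[None, :], -700, 700
    )
    ll_bar = float(np.sum(O * (np.log(E) + eta_bar) - E * np.exp(eta_bar) - const))
    d_at_mean = -2.0 * ll_bar
    p_d = dbar - d_at_mean
    return ModelFitStats(dbar=dbar, d_at_mean=d_at_mean, p_d=p_d, dic=dbar + p_d)


# ---------------------------------------------------------------------------
# draw persistence (columnar CSV)
# ---------------------------------------------------------------------------

def draws_to_frame(draws: PosteriorDraws) -> pd.DataFrame:
    cols = {"alpha": draws.alpha, "gamma": draws.gamma}
    for k, name in enumerate(draws.covariate_names):
        cols[f"beta:{name}"] = draws.beta[:, k]
    ids = draws.area_ids or list(range(1, draws.n_areas + 1))
    for block in ("s", "u", "delta"):
        arr = getattr(draws, block)
        for i, a in enumerate(ids):
            cols[f"{block}:{a}"] = arr[:, i]
    cols["tau_s"] = draws.tau_s
    cols["tau_u"] = draws.tau_u
    cols["tau_delta"] = draws.tau_delta
    return pd.DataFrame(cols)


def save_draws(draws: PosteriorDraws, path, header=None):
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        draws_to_frame(draws).to_csv(fh, index=False)


def load_draws(path) -> PosteriorDraws:
    df = pd.read_csv(path, comment="#")
    beta_cols = [c for c in df.columns if c.startswith("beta:")]
    s_cols = [c for c in df.columns if c.startswith("s:")]
    u_cols = [c for c in df.columns if c.startswith("u:")]
    d_cols = [c for c in df.columns if c.startswith("delta:")]
    area_ids = [c.split(":", 1)[1] for c in s_cols]
    return PosteriorDraws(
        alpha=df["alpha"].to_numpy(),
        gamma=df["gamma"].to_numpy(),
        beta=df[beta_cols].to_numpy() if beta_cols else np.zeros((len(df), 0)),
        s=df[s_cols].to_numpy(),
        u=df[u_cols].to_numpy(),
        delta=df[d_cols].to_numpy(),
        tau_s=df["tau_s"].to_numpy(),
        tau_u=df["tau_u"].to_numpy(),
        tau_delta=df["tau_delta"].to_numpy(),
        covariate_names=[c.split(":", 1)[1] for c in beta_cols],
        area_ids=area_ids,
        meta={"loaded_from": str(path)},
    )
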