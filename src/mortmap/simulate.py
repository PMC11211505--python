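"""Synthetic areal panels drawn from the spatio-temporal CAR Poisson model.

The generator is first-class: it defines the study conditions under which
every downstream stage (inference, risk mapping, model comparison) is
exercised without access to the original survey tables.  Counts are drawn

    O_it ~ Poisson(E_it * exp(alpha + s_i + u_i + X beta + (gamma + delta_i) t))

with s and delta sampled from the intrinsic CAR distribution on the supplied
graph (sum-to-zero per component), u iid Normal(0, 1/tau_u), and optional
area-level covariates correlated with the spatial surface s.

Default scales target state-level mortality-ratio magnitudes: with E = 1 and
alpha = log 80 the area means fall roughly in 20-250, and the default common
trend gamma = -0.12 per coded period matches the magnitude reported in
published national analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .car import center_sum_to_zero
from .design import encode_time, linear_predictor
from .panel import AdjacencyGraph, ArealPanel

__all__ = [
    "SimTruth",
    "make_lattice_graph",
    "make_srs_graph",
    "sample_icar",
    "simulate_panel",
    "SRS_STATES",
]

DEFAULT_ALPHA = float(np.log(80.0))
DEFAULT_GAMMA = -0.12
DEFAULT_TAU_S = 10.0
DEFAULT_TAU_U = 100.0
DEFAULT_TAU_DELTA = 10.0


@dataclass
class SimTruth:
    """Realised generative parameter values behind a simulated panel."""

    alpha: float
    gamma: float
    beta: np.ndarray
    s: np.ndarray
    u: np.ndarray
    delta: np.ndarray
    tau_s: float
    tau_u: float
    tau_delta: float
    seed: int | None = None

    def __post_init__(self):
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        self.s = np.asarray(self.s, dtype=float)
        self.u = np.asarray(self.u, dtype=float)
        self.delta = np.asarray(self.delta, dtype=float)
        for name in ("tau_s", "tau_u", "tau_delta"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("s", "delta"):
            v = getattr(self, name)
            if v.size and abs(v.sum()) > 1e-10:
                raise ValueError(f"{name} must sum to zero (got {v.sum():g})")

    def to_dict(self):
        return {
            "alpha": self.alpha,
            "gamma": self.gamma,
            "beta": self.beta.tolist(),
            "s": self.s.tolist(),
            "u": self.u.tolist(),
            "delta": self.delta.tolist(),
            "tau_s": self.tau_s,
            "tau_u": self.tau_u,
            "tau_delta": self.tau_delta,
            "seed": self.seed,
        }


def make_lattice_graph(rows: int, cols: int) -> AdjacencyGraph:
    """Rook-adjacency rectangular lattice (test geometry)."""
    if rows < 1 or cols < 1:
        raise ValueError("lattice dimensions must be positive")
    n = rows * cols
    neighbors = [[] for _ in range(n)]
    for r in range(rows):
        for c in range(cols):
            i = r * cols + c
            if c + 1 < cols:
                neighbors[i].append(i + 2)        # 1-based right neighbour
                neighbors[i + 1].append(i + 1)
            if r + 1 < rows:
                neighbors[i].append(i + cols + 1)
                neighbors[i + cols].append(i + 1)
    return AdjacencyGraph(n, [sorted(nbr) for nbr in neighbors])


# Legend: the 19 major states with sample-registration mortality estimates,
# in alphabetical order; graph node k (1-based) is SRS_STATES[k-1].
SRS_STATES = [
    "Andhra Pradesh",
    "Assam",
    "Bihar",
    "Chhattisgarh",
    "Gujarat",
    "Haryana",
    "Jharkhand",
    "Karnataka",
    "Kerala",
    "Madhya Pradesh",
    "Maharashtra",
    "Odisha",
    "Punjab",
    "Rajasthan",
    "Tamil Nadu",
    "Telangana",
    "Uttar Pradesh",
    "Uttarakhand",
    "West Bengal",
]

# Geographic contiguity restricted to the 19 states above (land borders with
# states outside the list are dropped).
_SRS_BORDERS = [
    ("Andhra Pradesh", "Telangana"),
    ("Andhra Pradesh", "Karnataka"),
    ("Andhra Pradesh", "Tamil Nadu"),
    ("Andhra Pradesh", "Odisha"),
    ("Andhra Pradesh", "Chhattisgarh"),
    ("Assam", "West Bengal"),
    ("Bihar", "Uttar Pradesh"),
    ("Bihar", "Jharkhand"),
    ("Bihar", "West Bengal"),
    ("Chhattisgarh", "Madhya Pradesh"),
    ("Chhattisgarh", "Maharashtra"),
    ("Chhattisgarh", "Telangana"),
    ("Chhattisgarh", "Odisha"),
    ("Chhattisgarh", "Jharkhand"),
    ("Chhattisgarh", "Uttar Pradesh"),
    ("Gujarat", "Rajasthan"),
    ("Gujarat", "Madhya Pradesh"),
    ("Gujarat", "Maharashtra"),
    ("Haryana", "Punjab"),
    ("Haryana", "Rajasthan"),
    ("Haryana", "Uttar Pradesh"),
    ("Haryana", "Uttarakhand"),
    ("Jharkhand", "Uttar Pradesh"),
    ("Jharkhand", "West Bengal"),
    ("Jharkhand", "Odisha"),
    ("Karnataka", "Kerala"),
    ("Karnataka", "Maharashtra"),
    ("Karnataka", "Tamil Nadu"),
    ("Karnataka", "Telangana"),
    ("Kerala", "Tamil Nadu"),
    ("Madhya Pradesh", "Maharashtra"),
    ("Madhya Pradesh", "Rajasthan"),
    ("Madhya Pradesh", "Uttar Pradesh"),
    ("Maharashtra", "Telangana"),
    ("Odisha", "West Bengal"),
    ("Punjab", "Rajasthan"),
    ("Rajasthan", "Uttar Pradesh"),
    ("Uttar Pradesh", "Uttarakhand"),
]


def make_srs_graph() -> AdjacencyGraph:
    """Fixed 19-node contiguity graph of the major-state panel (see legend)."""
    idx = {name: k + 1 for k, name in enumerate(SRS_STATES)}
    neighbors = [[] for _ in SRS_STATES]
    for a, b in _SRS_BORDERS:
        neighbors[idx[a] - 1].append(idx[b])
        neighbors[idx[b] - 1].append(idx[a])
    return AdjacencyGraph(len(SRS_STATES), [sorted(nbr) for nbr in neighbors])


def sample_icar(graph: AdjacencyGraph, tau: float, rng: np.random.Generator) -> np.ndarray:
    """Draw from the ICAR distribution restricted to the sum-to-zero subspace.

    Per connected component, samples from the zero-mean Gaussian whose
    precision is the pairwise-difference (Laplacian) matrix scaled by tau,
    using the pseudo-inverse covariance (eigenvectors with positive
    eigenvalue), then centers.  Islands get 0.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    x = np.zeros(graph.n)
    deg = graph.degrees.astype(float)
    A = np.zeros((graph.n, graph.n))
    if graph.n_edges:
        e = graph.edges
        A[e[:, 0], e[:, 1]] = 1.0
        A[e[:, 1], e[:, 0]] = 1.0
    for comp in graph.components:
        if len(comp) < 2:
            continue
        L = np.diag(deg[comp]) - A[np.ix_(comp, comp)]
        w, V = np.linalg.eigh(L)
        pos = w > 1e-10
        z = rng.standard_normal(int(pos.sum()))
        xi = V[:, pos] @ (z / np.sqrt(w[pos] * tau))
        x[comp] = xi - xi.mean()
    return x


def _truth_from_spec(graph, truth, covariate_spec, rng, seed):
    n = graph.n
    spec = dict(truth or {})
    alpha = float(spec.pop("alpha", DEFAULT_ALPHA))
    gamma = float(spec.pop("gamma", DEFAULT_GAMMA))
    tau_s = float(spec.pop("tau_s", DEFAULT_TAU_S))
    tau_u = float(spec.pop("tau_u", DEFAULT_TAU_U))
    tau_d = float(spec.pop("tau_delta", DEFAULT_TAU_DELTA))
    s = spec.pop("s", None)
    u = spec.pop("u", None)
    delta = spec.pop("delta", None)
    beta = spec.pop("beta", None)
    if spec:
        raise ValueError(f"unknown truth field(s) {sorted(spec)}")
    s = sample_icar(graph, tau_s, rng) if s is None else np.asarray(s, dtype=float)
    u = rng.standard_normal(n) / np.sqrt(tau_u) if u is None else np.asarray(u, dtype=float)
    delta = (
        sample_icar(graph, tau_d, rng) if delta is None else np.asarray(delta, dtype=float)
    )
    if covariate_spec:
        want = np.array([c.get("beta", 0.0) for c in covariate_spec], dtype=float)
        beta = want if beta is None else np.asarray(beta, dtype=float)
    else:
        beta = np.zeros(0) if beta is None else np.asarray(beta, dtype=float)
    return SimTruth(alpha, gamma, beta, s, u, delta, tau_s, tau_u, tau_d, seed=seed)


def _make_covariates(covariate_spec, s, rng):
    import pandas as pd

    n = len(s)
    sd = s.std()
    shat = (s - s.mean()) / sd if sd > 0 else np.zeros(n)
    cols = {}
    for c in covariate_spec:
        rho = float(c.get("corr_with_s", 0.0))
        if not -1 <= rho <= 1:
            raise ValueError("corr_with_s must lie in [-1, 1]")
        z = rng.standard_normal(n)
        cols[c["name"]] = rho * shat + np.sqrt(1 - rho**2) * z
    return pd.DataFrame(cols)


def simulate_panel(
    graph: AdjacencyGraph,
    truth=None,
    T: int = 5,
    expected="unit",
    covariate_spec=None,
    seed: int | None = None,
    time_coding: str = "centered",
    area_ids=None,
):
    """Simulate an :class:`ArealPanel` from the model; returns (panel, truth).

    ``truth`` may be a :class:`SimTruth` (used as-is) or a dict giving any of
    alpha, gamma, beta, s, u, delta, tau_s, tau_u, tau_delta; unspecified
    effects are drawn from their priors.  ``expected`` is ``"unit"``, a
    positive scalar, or an N x T matrix of positive expected counts.
    ``covariate_spec`` is a list of dicts with keys ``name``, optional
    ``corr_with_s`` and ``beta``.
    """
    if T < 1:
        raise ValueError("T must be positive")
    rng = np.random.default_rng(seed)
    n = graph.n

    if isinstance(expected, str):
        if expected != "unit":
            raise ValueError(f"unknown expected mode {expected!r}")
        E = np.ones((n, T))
        store_E = False
    else:
        E = np.asarray(expected, dtype=float)
        if E.ndim == 0:
            E = np.full((n, T), float(E))
        if E.shape != (n, T):
            raise ValueError(f"expected matrix must have shape {(n, T)}")
        if np.any(E <= 0):
            raise ValueError("expected counts must be positive in every cell")
        store_E = True

    if isinstance(truth, SimTruth):
        realized = truth
    else:
        realized = _truth_from_spec(graph, truth, covariate_spec, rng, seed)

    X = None
    Xmat = None
    if covariate_spec:
        X = _make_covariates(covariate_spec, realized.s, rng)
        Xmat = X.to_numpy()
    elif realized.beta.size:
        raise ValueError("truth has covariate effects but no covariate_spec was given")

    t = encode_time(T, time_coding)
    eta = linear_predictor(
        realized.alpha,
        realized.s,
        realized.u,
        realized.beta if realized.beta.size else None,
        Xmat,
        realized.gamma,
        realized.delta,
        t,
    )
    O = rng.poisson(E * np.exp(eta))

    if area_ids is None:
        area_ids = (
            list(SRS_STATES)
            if n == len(SRS_STATES) and graph.neighbors == make_srs_graph().neighbors
            else [f"area{i + 1:02d}" for i in range(n)]
        )
    if X is not None:
        X.index = area_ids
    panel = ArealPanel(
        area_ids,
        list(range(1, T + 1)),
        O,
        X=X,
        E=E if store_E else None,
    )
    return panel, realized
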