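"""Intrinsic conditional autoregressive (ICAR) prior mathematics.

The intrinsic CAR prior with unit adjacency weights puts, for an effect
vector x on a graph G with precision tau,

    log p(x) = ((n - c)/2) log tau - (tau/2) * sum_{i~j, i<j} (x_i - x_j)^2

up to an additive constant, where c is the number of connected components
(the rank deficiency of the graph Laplacian).  The full conditional of one
site is Normal(mean of neighbour values, 1/(tau * n_i)).  The prior is
improper: it is invariant to adding a constant per component, which is
resolved by sum-to-zero centering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .panel import AdjacencyGraph

__all__ = ["Hyperparams", "icar_logpdf", "icar_full_conditional", "center_sum_to_zero"]


@dataclass(frozen=True)
class Hyperparams:
    """Gamma(shape, rate) hyperpriors for the three precisions.

    Defaults Gamma(1, 0.0005) are a widespread vague disease-mapping choice
    (prior mean 2000, sd 2000 on each precision).
    """

    a_s: float = 1.0
    b_s: float = 0.0005
    a_u: float = 1.0
    b_u: float = 0.0005
    a_d: float = 1.0
    b_d: float = 0.0005

    def __post_init__(self):
        for name in ("a_s", "b_s", "a_u", "b_u", "a_d", "b_d"):
            if getattr(self, name) <= 0:
                raise ValueError(f"hyperparameter {name} must be positive")


def icar_logpdf(x, graph: AdjacencyGraph, tau: float) -> float:
    """Unnormalised ICAR log-density (additive constants dropped)."""
    x = np.asarray(x, dtype=float)
    if x.shape != (graph.n,):
        raise ValueError(f"x must have length {graph.n}")
    if tau <= 0:
        raise ValueError("tau must be positive")
    if graph.n_edges == 0:
        raise ValueError("ICAR prior is undefined on an edgeless graph")
    a, b = graph.edges[:, 0], graph.edges[:, 1]
    pairwise = float(np.sum((x[a] - x[b]) ** 2))
    rank = graph.n - graph.n_components
    return 0.5 * rank * np.log(tau) - 0.5 * tau * pairwise


def icar_full_conditional(i: int, x, graph: AdjacencyGraph, tau: float):
    """Mean and variance of x_i given its neighbours: (nbr mean, 1/(tau*n_i)).

    ``i`` is a 0-based area index.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    x = np.asarray(x, dtype=float)
    nbr = graph.neighbors0[i]
    if len(nbr) == 0:
        raise ValueError(
            f"area index {i} is an island; its spatial effect is fixed at 0 "
            "and its variation must be carried by the unstructured effect"
        )
    return float(x[nbr].mean()), 1.0 / (tau * len(nbr))


def center_sum_to_zero(x) -> np.ndarray:
    """Subtract the mean so the result sums to zero (within 1e-12)."""
    x = np.asarray(x, dtype=float)
    if x.size < 1:
        raise ValueError("need at least one element")
    return x - x.mean()
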