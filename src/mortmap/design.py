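"""Model definitions: time coding, design matrix, linear predictor, likelihood.

The linear predictor of the spatio-temporal model is

    eta_it = log rho_it
           = alpha + s_i + u_i + sum_k beta_k x_ik + (gamma + delta_i) * time_t

with s a spatially structured (ICAR) effect, u an unstructured iid effect,
gamma a common linear time trend and delta_i the area-specific deviation
from it (also ICAR).  Model 1 has no covariates; model 2 adds six
maternal-health covariates; model 3 adds eleven health-system covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .car import Hyperparams
from .panel import ArealPanel
from .standardize import zscale_columns

__all__ = [
    "MODEL2_COVARIATES",
    "MODEL3_COVARIATES",
    "ModelSpec",
    "encode_time",
    "linear_predictor",
    "poisson_loglik",
    "build_design",
]

MODEL2_COVARIATES = (
    "anemia",
    "low_bmi",
    "low_birth_interval",
    "contraception",
    "c_section",
    "birth_order_gt3",
)

MODEL3_COVARIATES = (
    "anc",
    "pnc",
    "institutional_delivery",
    "health_index",
    "accreditation",
    "nqas",
    "ghe",
    "oope",
    "jsy",
    "population",
    "skilled_attendance",
)


@dataclass(frozen=True)
class ModelSpec:
    """Which covariates and structural components enter the model.

    The component switches exist for diagnostics (e.g. an intercept-only
    fit); the shipped model variants 1-3 keep all of them on.
    """

    model_id: str = "1"
    covariate_names: tuple = ()
    time_coding: str = "centered"
    standardize_covariates: bool = True
    hyper: Hyperparams = field(default_factory=Hyperparams)
    spatial: bool = True
    unstructured: bool = True
    trend: bool = True
    interaction: bool = True

    def __post_init__(self):
        if self.time_coding not in ("centered", "raw"):
            raise ValueError("time_coding must be 'centered' or 'raw'")
        object.__setattr__(self, "covariate_names", tuple(self.covariate_names))

    @classmethod
    def model1(cls, **kw):
        return cls(model_id="1", covariate_names=(), **kw)

    @classmethod
    def model2(cls, **kw):
        return cls(model_id="2", covariate_names=MODEL2_COVARIATES, **kw)

    @classmethod
    def model3(cls, **kw):
        return cls(model_id="3", covariate_names=MODEL3_COVARIATES, **kw)

    @classmethod
    def custom(cls, covariate_names, **kw):
        return cls(model_id="custom", covariate_names=tuple(covariate_names), **kw)


def encode_time(T: int, coding: str = "centered") -> np.ndarray:
    """Coded time values for T periods: raw (1..T) or centered (sum 0)."""
    if T < 1:
        raise ValueError("T must be positive")
    t = np.arange(1, T + 1, dtype=float)
    if coding == "raw":
        return t
    if coding == "centered":
        return t - t.mean()
    raise ValueError(f"unknown time coding {coding!r}")


def linear_predictor(alpha, s, u, beta, X, gamma, delta, time) -> np.ndarray:
    """eta_it = alpha + s_i + u_i + sum_k beta_k x_ik + (gamma + delta_i) time_t."""
    s = np.asarray(s, dtype=float)
    u = np.asarray(u, dtype=float)
    delta = np.asarray(delta, dtype=float)
    time = np.asarray(time, dtype=float)
    N = s.shape[0]
    if u.shape != (N,) or delta.shape != (N,):
        raise ValueError("s, u, delta must share length N")
    beta = np.zeros(0) if beta is None else np.atleast_1d(np.asarray(beta, dtype=float))
    if beta.size:
        X = np.asarray(X, dtype=float)
        if X.shape != (N, beta.size):
            raise ValueError(f"X must have shape {(N, beta.size)}, got {X.shape}")
        xb = X @ beta
    else:
        xb = np.zeros(N)
    level = alpha + s + u + xb
    slope = gamma + delta
    return level[:, None] + slope[:, None] * time[None, :]


def poisson_loglik(O, E, eta) -> float:
    """Poisson log-likelihood sum_it [O log(E e^eta) - E e^eta - log O!].

    The log-factorial term is retained so deviances are absolute and
    comparable across models.  eta is clipped at +/-700 before
    exponentiation; clips are counted on ``poisson_loglik.n_clipped``.
    """
    O = np.asarray(O, dtype=float)
    E = np.asarray(E, dtype=float)
    eta = np.asarray(eta, dtype=float)
    if O.shape != E.shape or O.shape != eta.shape:
        raise ValueError("O, E, eta must share a shape")
    if np.any(E <= 0):
        raise ValueError("expected counts must be positive")
    clipped = np.abs(eta) > 700
    if clipped.any():
        poisson_loglik.n_clipped += int(clipped.sum())
    eta = np.clip(eta, -700, 700)
    mu = E * np.exp(eta)
    return float(np.sum(O * (np.log(E) + eta) - mu - gammaln(O + 1)))


poisson_loglik.n_clipped = 0


def build_design(panel: ArealPanel, spec: ModelSpec):
    """Covariate design matrix (N x K) in spec order, optionally z-scaled."""
    names = list(spec.covariate_names)
    if not names:
        return np.zeros((panel.n_areas, 0)), []
    have = panel.covariate_names
    missing = [n for n in names if n not in have]
    if missing:
        raise ValueError(f"panel is missing covariate(s) {missing}")
    X = panel.X[names].to_numpy(dtype=float)
    if spec.standardize_covariates:
        X = zscale_columns(X)
    return X, names
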