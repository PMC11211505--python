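"""Expected counts and heatmap column standardization."""

from __future__ import annotations

import numpy as np

from .panel import ArealPanel

__all__ = ["expected_counts", "zscale_columns"]


def expected_counts(panel: ArealPanel, mode: str = "unit") -> np.ndarray:
    """Expected counts E_it for the Poisson model O_it ~ Poisson(E_it rho_it).

    mode="unit"
        All ones.  This is the convention when the observed quantity is
        already a ratio standardised to a common denominator (a mortality
        ratio per 100,000 live births), so rho_it is read directly on the
        count scale.
    mode="internal"
        Per-period internal standardization
        E_it = P_it * (sum_i O_it / sum_i P_it), requiring denominators P.
        Within every period, sum_i E_it = sum_i O_it by construction.
    """
    N, T = panel.n_areas, panel.n_times
    if mode == "unit":
        return np.ones((N, T))
    if mode == "internal":
        if panel.P is None:
            raise ValueError("internal standardization requires population denominators P")
        rate = panel.O.sum(axis=0) / panel.P.sum(axis=0)
        return panel.P * rate[None, :]
    raise ValueError(f"unknown expected-counts mode {mode!r}")


def zscale_columns(M) -> np.ndarray:
    """Scale each column to mean 0 and sample (n-1) standard deviation 1.

    Constant columns map to all zeros rather than NaN.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 2:
        raise ValueError("expected a 2-D matrix")
    if M.shape[0] < 2:
        raise ValueError("column standardization needs at least 2 rows")
    mean = M.mean(axis=0)
    sd = M.std(axis=0, ddof=1)
    out = M - mean[None, :]
    nz = sd > 0
    out[:, nz] /= sd[None, nz]
    out[:, ~nz] = 0.0
    return out
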