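"""Post-inference spatial statistics: relative risk, exceedance, hot spots.

The spatial relative risk of area i is rho_i = exp(s_hat_i), the exponential
of the posterior mean of the structured spatial effect; the exceedance
probability p_i = P(rho_i > 1 | data) is the fraction of posterior draws
with s_i > 0.  Areas with p_i strictly above the threshold (default 0.5)
are labelled hot spots, all others cold spots.  The interaction effect
delta_i is the area-specific deviation of the linear time trend from the
common trend; a positive posterior mean marks locally rising risk.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .sampler import PosteriorDraws

__all__ = [
    "spatial_risk",
    "exceedance_prob",
    "classify_areas",
    "interaction_trend_summary",
    "make_risk_report",
]


def spatial_risk(draws: PosteriorDraws) -> np.ndarray:
    """exp(posterior mean of s_i) per area — not mean(exp(s))."""
    return np.exp(draws.s.mean(axis=0))


def exceedance_prob(draws: PosteriorDraws) -> np.ndarray:
    """Per area, the fraction of retained draws with s_i > 0."""
    return (draws.s > 0).mean(axis=0)


def classify_areas(p, threshold: float = 0.5) -> np.ndarray:
    """Label areas 'hot' iff p > threshold (strict), else 'cold'."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie strictly between 0 and 1")
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("exceedance probabilities must lie in [0, 1]")
    return np.where(p > threshold, "hot", "cold")


def interaction_trend_summary(draws: PosteriorDraws) -> pd.DataFrame:
    """Posterior mean and equal-tailed 95% CI of delta_i, with direction.

    direction is 'rising' for a strictly positive posterior mean and
    'declining' otherwise (an exactly-zero mean counts as declining).
    """
    mean = draws.delta.mean(axis=0)
    lo = np.percentile(draws.delta, 2.5, axis=0)
    hi = np.percentile(draws.delta, 97.5, axis=0)
    ids = draws.area_ids or list(range(1, draws.n_areas + 1))
    return pd.DataFrame(
        {
            "area_id": ids,
            "delta_mean": mean,
            "delta_lo": lo,
            "delta_hi": hi,
            "direction": np.where(mean > 0, "rising", "declining"),
        }
    )


def make_risk_report(draws: PosteriorDraws, threshold: float = 0.5) -> pd.DataFrame:
    """Combined per-area risk report (spatial RR, exceedance, label, trend)."""
    p = exceedance_prob(draws)
    trend = interaction_trend_summary(draws)
    return pd.DataFrame(
        {
            "area_id": trend["area_id"],
            "spatial_rr": spatial_risk(draws),
            "exceed_prob": p,
            "label": classify_areas(p, threshold),
            "delta_mean": trend["delta_mean"],
            "delta_lo": trend["delta_lo"],
            "delta_hi": trend["delta_hi"],
        }
    )
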