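"""Descriptive layer: per-area linear trend fits and heatmap matrices."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .panel import ArealPanel
from .standardize import zscale_columns

__all__ = ["TrendFit", "fit_area_trend", "fit_panel_trends", "heatmap_matrix"]


@dataclass
class TrendFit:
    """Ordinary least-squares linear trend for one area's series."""

    area_id: object
    slope: float
    intercept: float
    slope_se: float
    slope_lo: float
    slope_hi: float
    r2: float

    def to_dict(self):
        return {
            "area_id": self.area_id,
            "slope": self.slope,
            "intercept": self.intercept,
            "slope_se": self.slope_se,
            "slope_lo": self.slope_lo,
            "slope_hi": self.slope_hi,
            "r2": self.r2,
        }


def fit_area_trend(y, t, area_id=None) -> TrendFit:
    """OLS fit y = intercept + slope * t with a t-distribution 95% CI.

    The CI uses t_{0.975, T-2}: with the very short series typical of this
    application a normal interval would be badly anti-conservative.  With
    T = 2 the point fit is returned with an infinite CI; a zero-variance
    response gets r2 = 0 by convention.
    """
    y = np.asarray(y, dtype=float)
    t = np.asarray(t, dtype=float)
    if y.shape != t.shape or y.ndim != 1:
        raise ValueError("y and t must be equal-length vectors")
    T = len(y)
    if T < 2:
        raise ValueError("need at least 2 time points")
    if np.ptp(t) == 0:
        raise ValueError("time values have zero variance")

    res = sm.OLS(y, sm.add_constant(t)).fit()
    intercept, slope = res.params
    if T == 2:
        se, lo, hi = np.inf, -np.inf, np.inf
    else:
        se = float(res.bse[1])
        lo, hi = (float(v) for v in res.conf_int(alpha=0.05)[1])
    r2 = 0.0 if np.ptp(y) == 0 else float(res.rsquared)
    return TrendFit(area_id, float(slope), float(intercept), se, lo, hi, r2)


def fit_panel_trends(panel: ArealPanel, time_values=None) -> pd.DataFrame:
    """One OLS trend fit per area; time defaults to 1..T."""
    t = np.arange(1, panel.n_times + 1, dtype=float) if time_values is None else np.asarray(
        time_values, dtype=float
    )
    rows = [
        fit_area_trend(panel.O[i], t, area_id=a).to_dict()
        for i, a in enumerate(panel.area_ids)
    ]
    return pd.DataFrame(rows)


def heatmap_matrix(panel: ArealPanel, orientation: str = "by_column",
                   with_covariates: bool = False):
    """Column-standardised matrix for heatmap display.

    by_column: rows are areas, each time column scaled to mean 0 / sd 1.
    by_row:    the transpose is scaled, i.e. each area's own series is
               standardised (rows become times).
    with_covariates (by_column only): the matrix is [per-area mean count,
    covariates], one standardised column per feature.

    Returns (matrix, row_labels, col_labels).
    """
    if with_covariates:
        if orientation != "by_column":
            raise ValueError("covariate heatmaps are column-oriented")
        cols = {"observed_mean": panel.O.mean(axis=1)}
        if panel.X is not None:
            for name in panel.covariate_names:
                cols[name] = panel.X[name].to_numpy()
        M = np.column_stack(list(cols.values()))
        return zscale_columns(M), list(panel.area_ids), list(cols)
    if orientation == "by_column":
        return zscale_columns(panel.O), list(panel.area_ids), list(panel.time_ids)
    if orientation == "by_row":
        return zscale_columns(panel.O.T), list(panel.time_ids), list(panel.area_ids)
    raise ValueError(f"unknown orientation {orientation!r}")
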