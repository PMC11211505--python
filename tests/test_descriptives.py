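"""Per-area OLS trend fits and heatmap matrices."""

import numpy as np
import pytest
from scipy import stats

from mortmap import (
    fit_area_trend,
    fit_panel_trends,
    heatmap_matrix,
    make_lattice_graph,
    simulate_panel,
)


def _ols_oracle(y, t):
    """Independent normal-equations OLS with t-based 95% CI."""
    T = len(y)
    A = np.column_stack([np.ones(T), t])
    coef = np.linalg.solve(A.T @ A, A.T @ y)
    resid = y - A @ coef
    sigma2 = resid @ resid / (T - 2)
    cov = sigma2 * np.linalg.inv(A.T @ A)
    se = np.sqrt(cov[1, 1])
    tcrit = stats.t.ppf(0.975, T - 2)
    return coef[1], coef[0], se, coef[1] - tcrit * se, coef[1] + tcrit * se


def test_perfect_linear_fit():
    t = np.arange(1.0, 6.0)
    fit = fit_area_trend(2 * t + 1, t)
    assert np.isclose(fit.slope, 2.0)
    assert np.isclose(fit.intercept, 1.0)
    assert np.isclose(fit.slope_se, 0.0, atol=1e-10)
    assert np.isclose(fit.slope_lo, 2.0, atol=1e-8)
    assert np.isclose(fit.slope_hi, 2.0, atol=1e-8)
    assert np.isclose(fit.r2, 1.0)


def test_constant_response():
    t = np.arange(1.0, 6.0)
    fit = fit_area_trend(np.full(5, 7.0), t)
    assert np.isclose(fit.slope, 0.0, atol=1e-12)
    assert fit.r2 == 0.0


def test_matches_normal_equations_oracle():
    rng = np.random.default_rng(9)
    t = np.arange(1.0, 9.0)
    for _ in range(10):
        y = rng.normal(50 - 3 * t, 5.0)
        fit = fit_area_trend(y, t)
        slope, intercept, se, lo, hi = _ols_oracle(y, t)
        assert np.isclose(fit.slope, slope, atol=1e-10)
        assert np.isclose(fit.intercept, intercept, atol=1e-10)
        assert np.isclose(fit.slope_se, se, atol=1e-10)
        assert np.isclose(fit.slope_lo, lo, atol=1e-10)
        assert np.isclose(fit.slope_hi, hi, atol=1e-10)


def test_scale_equivariance():
    rng = np.random.default_rng(10)
    t = np.arange(1.0, 7.0)
    y = rng.normal(10.0, 2.0, 6)
    f1 = fit_area_trend(y, t)
    f3 = fit_area_trend(3.0 * y, t)
    assert np.isclose(f3.slope, 3 * f1.slope)
    assert np.isclose(f3.slope_lo, 3 * f1.slope_lo)
    assert np.isclose(f3.slope_hi, 3 * f1.slope_hi)


def test_degenerate_inputs():
    with pytest.raises(ValueError, match="2 time points"):
        fit_area_trend([1.0], [1.0])
    with pytest.raises(ValueError, match="zero variance"):
        fit_area_trend([1.0, 2.0], [3.0, 3.0])
    fit = fit_area_trend([1.0, 5.0], [0.0, 1.0])  # T=2: point fit, infinite CI
    assert np.isclose(fit.slope, 4.0)
    assert fit.slope_lo == -np.inf and fit.slope_hi == np.inf


def test_ci_contains_slope_on_panel(srs_graph):
    panel, _ = simulate_panel(srs_graph, T=5, seed=13)
    table = fit_panel_trends(panel)
    assert len(table) == 19
    assert (table["slope_lo"] <= table["slope"]).all()
    assert (table["slope"] <= table["slope_hi"]).all()


def test_negative_common_trend_yields_negative_slopes(srs_graph):
    """gamma < 0 with delta = 0: most areas get a negative OLS slope."""
    neg = total = 0
    for rep in range(20):
        panel, _ = simulate_panel(
            srs_graph,
            truth=dict(gamma=-0.12, delta=np.zeros(19)),
            T=5, seed=500 + rep,
        )
        slopes = fit_panel_trends(panel)["slope"]
        neg += int((slopes < 0).sum())
        total += len(slopes)
    assert neg / total > 0.5


def test_heatmap_by_column_scaling(srs_graph):
    panel, _ = simulate_panel(srs_graph, T=5, seed=14)
    M, rows, cols = heatmap_matrix(panel, "by_column")
    assert (len(rows), len(cols)) == (19, 5)
    assert np.all(np.abs(M.mean(axis=0)) < 1e-12)
    assert np.all(np.abs(M.std(axis=0, ddof=1) - 1) < 1e-12)


def test_heatmap_orientation_duality(srs_graph):
    panel, _ = simulate_panel(srs_graph, T=5, seed=15)
    by_col, _, _ = heatmap_matrix(panel, "by_column")
    by_row, rows, cols = heatmap_matrix(panel, "by_row")
    from mortmap import zscale_columns

    np.testing.assert_allclose(by_row, zscale_columns(panel.O.T), atol=1e-12)
    assert rows == panel.time_ids and cols == panel.area_ids


def test_heatmap_with_covariates(srs_graph):
    panel, _ = simulate_panel(
        srs_graph, T=5, seed=16,
        covariate_spec=[{"name": "anc", "beta": 0.0},
                        {"name": "jsy", "beta": 0.0}],
    )
    M, rows, cols = heatmap_matrix(panel, with_covariates=True)
    assert M.shape == (19, 3)  # mean count + K covariates
    assert cols == ["observed_mean", "anc", "jsy"]
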