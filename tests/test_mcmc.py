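"""Sampler contracts: determinism, oracles, summaries, DIC identities."""

import numpy as np
import pytest

from mortmap import (
    Hyperparams,
    ModelSpec,
    PosteriorDraws,
    compute_dic,
    load_draws,
    make_lattice_graph,
    rr_transform,
    run_mcmc,
    save_draws,
    simulate_panel,
    summarize_draws,
)


def _fixed_effects_only():
    return ModelSpec.custom([], spatial=False, unstructured=False,
                            trend=False, interaction=False)


@pytest.fixture(scope="module")
def small_fit():
    g = make_lattice_graph(2, 3)
    panel, truth = simulate_panel(g, T=4, seed=21)
    draws = run_mcmc(panel, g, ModelSpec.model1(), iters=900, burnin=400,
                     thin=1, chains=2, seed=77)
    return g, panel, draws


def test_same_seed_bitwise_identical(small_fit):
    g, panel, draws = small_fit
    again = run_mcmc(panel, g, ModelSpec.model1(), iters=900, burnin=400,
                     thin=1, chains=2, seed=77)
    for name in ("alpha", "gamma", "s", "u", "delta", "tau_s", "tau_u", "tau_delta"):
        np.testing.assert_array_equal(getattr(draws, name), getattr(again, name))


def test_fields_centered_per_draw(small_fit):
    _, _, draws = small_fit
    assert np.all(np.abs(draws.s.sum(axis=1)) < 1e-8)
    assert np.all(np.abs(draws.delta.sum(axis=1)) < 1e-8)


def test_draws_roundtrip_csv(tmp_path, small_fit):
    _, _, draws = small_fit
    save_draws(draws, tmp_path / "d.csv", header="seed=77")
    back = load_draws(tmp_path / "d.csv")
    np.testing.assert_allclose(back.s, draws.s, rtol=1e-12)
    assert back.area_ids == [str(a) for a in draws.area_ids]


def test_intercept_only_posterior_matches_mle():
    """With no random effects the posterior mean of alpha is ~log(mean O)."""
    g = make_lattice_graph(4, 5)
    panel, _ = simulate_panel(
        g, truth=dict(alpha=4.0, gamma=0.0, s=np.zeros(20), u=np.zeros(20),
                      delta=np.zeros(20)),
        T=5, seed=31,
    )
    draws = run_mcmc(panel, g, _fixed_effects_only(), iters=4000, burnin=1000,
                     thin=1, chains=1, seed=32)
    mle = np.log(panel.O.mean())
    a = draws.alpha
    # batch-means Monte-Carlo standard error
    nb = 20
    batches = a[: len(a) // nb * nb].reshape(nb, -1).mean(axis=1)
    mcse = batches.std(ddof=1) / np.sqrt(nb)
    assert abs(a.mean() - mle) < 3 * mcse + 2e-3


def test_iters_must_exceed_burnin(small_fit):
    g, panel, _ = small_fit
    with pytest.raises(ValueError, match="exceed"):
        run_mcmc(panel, g, ModelSpec.model1(), iters=100, burnin=100, seed=1)


def test_seed_required(small_fit):
    g, panel, _ = small_fit
    with pytest.raises(ValueError, match="seed"):
        run_mcmc(panel, g, ModelSpec.model1(), iters=200, burnin=100, seed=None)


# -- summaries --------------------------------------------------------------

def _const_draws(c, n=200, N=3):
    one = np.full(n, c)
    fld = np.full((n, N), 0.0)
    return PosteriorDraws(alpha=one, gamma=one, beta=np.zeros((n, 0)),
                          s=fld, u=fld, delta=fld, tau_s=one + 2, tau_u=one + 2,
                          tau_delta=one + 2, area_ids=["a", "b", "c"])


def test_summary_point_mass():
    summ = summarize_draws(_const_draws(1.5))
    row = summ.loc["alpha"]
    assert row["mean"] == 1.5 and row["q2.5"] == 1.5 and row["q97.5"] == 1.5


def test_summary_requires_100_draws():
    with pytest.raises(ValueError, match="100"):
        summarize_draws(_const_draws(1.0, n=50))


def test_summary_normal_quantiles():
    n = 100000
    zeros = np.zeros(n)
    d = PosteriorDraws(
        alpha=np.random.default_rng(8).standard_normal(n), gamma=zeros,
        beta=np.zeros((n, 0)), s=np.zeros((n, 3)), u=np.zeros((n, 3)),
        delta=np.zeros((n, 3)), tau_s=zeros + 1, tau_u=zeros + 1,
        tau_delta=zeros + 1, area_ids=["a", "b", "c"],
    )
    summ = summarize_draws(d)
    assert abs(summ.loc["alpha", "q2.5"] + 1.96) < 0.02
    assert abs(summ.loc["alpha", "q97.5"] - 1.96) < 0.02


def test_summary_chain_order_invariant(small_fit):
    _, _, draws = small_fit
    perm = np.random.default_rng(0).permutation(draws.n_draws)
    shuffled = PosteriorDraws(
        alpha=draws.alpha[perm], gamma=draws.gamma[perm], beta=draws.beta[perm],
        s=draws.s[perm], u=draws.u[perm], delta=draws.delta[perm],
        tau_s=draws.tau_s[perm], tau_u=draws.tau_u[perm],
        tau_delta=draws.tau_delta[perm], covariate_names=draws.covariate_names,
        area_ids=draws.area_ids,
    )
    np.testing.assert_allclose(
        summarize_draws(draws)[["mean", "q2.5", "q97.5"]].to_numpy(),
        summarize_draws(shuffled)[["mean", "q2.5", "q97.5"]].to_numpy(),
        rtol=1e-12,
    )


@pytest.mark.parametrize(
    "coef,rr", [(-0.720, 0.486752), (0.0, 1.0), (0.4939, 1.638695)]
)
def test_rr_transform(coef, rr):
    assert np.isclose(rr_transform(coef), rr, rtol=1e-5)


def test_rr_is_exp_of_mean_not_mean_of_exp(small_fit):
    _, _, draws = small_fit
    summ = summarize_draws(draws)
    assert np.isclose(
        summ.loc["alpha", "rr"], rr_transform(draws.alpha.mean()), rtol=1e-12
    )
    assert not np.isclose(summ.loc["alpha", "rr"], np.exp(draws.alpha).mean(),
                          rtol=1e-6)


# -- DIC --------------------------------------------------------------------

def test_dic_point_mass_draws(small_fit):
    g, panel, draws = small_fit
    idx = np.zeros(150, dtype=int)
    pm = PosteriorDraws(
        alpha=draws.alpha[idx], gamma=draws.gamma[idx], beta=draws.beta[idx],
        s=draws.s[idx], u=draws.u[idx], delta=draws.delta[idx],
        tau_s=draws.tau_s[idx], tau_u=draws.tau_u[idx], tau_delta=draws.tau_delta[idx],
        area_ids=draws.area_ids,
    )
    stats = compute_dic(pm, panel, 1.0, ModelSpec.model1())
    assert abs(stats.p_d) < 1e-9
    assert np.isclose(stats.dic, stats.d_at_mean, atol=1e-9)


def test_dic_algebraic_identity(small_fit):
    g, panel, draws = small_fit
    stats = compute_dic(draws, panel, 1.0, ModelSpec.model1())
    assert np.isclose(stats.dic, stats.dbar + stats.p_d, atol=1e-9)
    assert np.isclose(stats.dic, 2 * stats.dbar - stats.d_at_mean, atol=1e-9)


# -- prior-only sampling ----------------------------------------------------

def test_prior_only_recovers_tau_u_hyperprior():
    """Likelihood off: tau_u draws reproduce Gamma(2, 1) moments."""
    g = make_lattice_graph(3, 3)
    panel, _ = simulate_panel(g, T=3, seed=41)
    spec = ModelSpec.model1(hyper=Hyperparams(a_u=2.0, b_u=1.0))
    draws = run_mcmc(panel, g, spec, iters=21000, burnin=1000, thin=2,
                     chains=1, seed=42, use_likelihood=False)
    assert abs(draws.tau_u.mean() - 2.0) < 0.15
    assert abs(draws.tau_u.var() - 2.0) < 0.5
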