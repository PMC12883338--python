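"""Gibbs sampler correctness: conjugate closed forms, GLS limit,
posterior summaries and shrinkage diagnostics."""

import numpy as np
import pandas as pd
import pytest

from demosae.sae import (
    AUX_DEFAULT_COLUMNS,
    ChainConfig,
    GibbsDraws,
    PriorSpec,
    SAEModel,
    build_model,
    gibbs_sample,
    lag1_autocorrelation,
    shrinkage_weights,
    summarize,
)


def _aux_frame(rng, D):
    aux = pd.DataFrame({"district_id": [f"D{i:03d}" for i in range(D)]})
    for c in AUX_DEFAULT_COLUMNS:
        aux[c] = rng.standard_normal(D)
    return aux


def _direct_frame(ids, values, variances, n_eff=25.0):
    return pd.DataFrame(
        {
            "district_id": ids,
            "value": values,
            "sampling_variance": variances,
            "effective_size": n_eff,
        }
    )


@pytest.fixture(scope="module")
def fh_fixture():
    """Area-level data simulated from the model itself (log link)."""
    rng = np.random.default_rng(21)
    D = 60
    aux = _aux_frame(rng, D)
    Z = aux[list(AUX_DEFAULT_COLUMNS)].to_numpy()
    Zs = (Z - Z.mean(0)) / Z.std(0)
    X = np.column_stack([np.ones(D), Zs])
    beta = np.array([0.8, 0.1, -0.05, 0.03, -0.08])
    sigma_u2 = 0.02
    gamma = np.full(D, 0.01)
    eta = X @ beta + rng.normal(0, np.sqrt(sigma_u2), D)
    y = eta + rng.normal(0, np.sqrt(gamma))
    direct = _direct_frame(
        aux["district_id"], np.exp(y), gamma * np.exp(y) ** 2
    )
    return direct, aux, X, beta, sigma_u2, gamma, y, eta


def test_build_model_shapes_and_link(fh_fixture):
    direct, aux, X, *_ , y, _ = fh_fixture
    m = build_model(direct, aux, link="log")
    assert m.X.shape == (60, 5)
    np.testing.assert_allclose(m.y, y, rtol=1e-10)
    np.testing.assert_allclose(m.X, X, rtol=1e-10)


def test_logit_delta_method_variance():
    aux = _aux_frame(np.random.default_rng(0), 1)
    direct = _direct_frame(aux["district_id"], [250.0], [0.0001])
    m = build_model(direct, aux, link="logit")
    assert m.y[0] == pytest.approx(np.log(0.25 / 0.75))
    assert m.gamma_hat[0] == pytest.approx(0.0001 / (0.25 * 0.75) ** 2)


def test_missing_auxiliary_row_is_reported():
    rng = np.random.default_rng(0)
    aux = _aux_frame(rng, 3)
    direct = _direct_frame(["D000", "D001", "D002", "D999"],
                           [2.0] * 4, [0.01] * 4)
    with pytest.raises(ValueError, match="D999"):
        build_model(direct, aux, link="log")


def test_single_district_conjugate_shrinkage():
    # Normal-Normal with unit variances: direct 2.0, prior mean 1.0
    # => posterior mean 1.5 with equal weights
    model = SAEModel(
        district_ids=["A"], y=np.array([2.0]), gamma_hat=np.array([1.0]),
        nu=np.array([1.0]), X=np.ones((1, 1)), link="log", per_1000=False,
        priors=PriorSpec(), aux_columns=(), direct_values=np.array([np.e**2]),
    )
    draws = gibbs_sample(
        model,
        ChainConfig(n_iterations=20_000, burn_in=1_000, thin_k=1,
                    n_chains=2, seed=5),
        fixed={"beta": np.array([1.0]), "sigma_u2": 1.0,
               "gamma": np.array([1.0])},
    )
    n = draws.theta.size
    mc_se = draws.theta.std() / np.sqrt(n)
    assert draws.theta.mean() == pytest.approx(1.5, abs=3 * max(mc_se, 1e-3))
    assert draws.theta.var() == pytest.approx(0.5, rel=0.1)


def test_fixed_variances_reduce_to_gls(fh_fixture):
    direct, aux, X = fh_fixture[0], fh_fixture[1], fh_fixture[2]
    m = build_model(direct, aux, link="log")
    draws = gibbs_sample(
        m,
        ChainConfig(n_iterations=11_000, burn_in=1_000, thin_k=1,
                    n_chains=1, seed=17),
        fixed={"sigma_u2": 0.0, "gamma": m.gamma_hat},
    )
    W = np.diag(1.0 / m.gamma_hat)
    gls = np.linalg.solve(X.T @ W @ X, X.T @ W @ m.y)
    flat = draws.beta.reshape(-1, 5)
    mc_se = flat.std(axis=0, ddof=1) / np.sqrt(flat.shape[0])
    np.testing.assert_array_less(
        np.abs(flat.mean(axis=0) - gls), 3 * mc_se + 1e-4
    )


def test_same_seed_identical_draws(fh_fixture):
    direct, aux = fh_fixture[0], fh_fixture[1]
    m = build_model(direct, aux, link="log")
    cfg = ChainConfig(n_iterations=500, burn_in=100, thin_k=2,
                      n_chains=2, seed=33)
    d1 = gibbs_sample(m, cfg)
    d2 = gibbs_sample(m, cfg)
    np.testing.assert_array_equal(d1.theta, d2.theta)
    np.testing.assert_array_equal(d1.beta, d2.beta)


def _draws_from_theta(theta, model, chain):
    C, R, D = theta.shape
    return GibbsDraws(
        beta=np.zeros((C, R, 1)),
        sigma_u2=np.ones((C, R)),
        theta=theta,
        gamma=np.ones((C, R, D)),
        model=model,
        chain=chain,
    )


def _dummy_model(D=1):
    return SAEModel(
        district_ids=[f"D{i}" for i in range(D)],
        y=np.zeros(D), gamma_hat=np.ones(D), nu=np.ones(D),
        X=np.ones((D, 1)), link="log", per_1000=False,
        priors=PriorSpec(), aux_columns=(),
        direct_values=np.ones(D),
    )


def test_summary_of_constant_draws_is_degenerate():
    chain = ChainConfig(n_iterations=200, burn_in=0, thin_k=1,
                        n_chains=2, seed=0)
    theta = np.full((2, 200, 1), np.log(3.0))
    s = summarize(_draws_from_theta(theta, _dummy_model(), chain))
    row = s.districts.iloc[0]
    assert row["posterior_mean"] == pytest.approx(3.0)
    assert row["ci_low"] == pytest.approx(3.0)
    assert row["ci_high"] == pytest.approx(3.0)


def test_credible_interval_matches_normal_quantiles():
    rng = np.random.default_rng(3)
    theta = rng.standard_normal((2, 50_000, 1))
    chain = ChainConfig(n_iterations=50_000, burn_in=0, thin_k=1,
                        n_chains=2, seed=0)
    s = summarize(_draws_from_theta(theta, _dummy_model(), chain))
    # log link: the interval of exp(theta) has endpoints exp(+-1.645)
    row = s.districts.iloc[0]
    assert np.log(row["ci_low"]) == pytest.approx(-1.645, abs=0.02)
    assert np.log(row["ci_high"]) == pytest.approx(1.645, abs=0.02)


def test_identical_chains_have_unit_rhat(fh_fixture):
    direct, aux = fh_fixture[0], fh_fixture[1]
    m = build_model(direct, aux, link="log")
    cfg = ChainConfig(n_iterations=3_000, burn_in=500, thin_k=5,
                      n_chains=2, seed=2)
    s = summarize(gibbs_sample(m, cfg))
    assert s.diagnostics["rhat_beta_max"] < 1.05
    assert s.diagnostics["rhat_sigma_u2"] < 1.1


def test_thinning_reduces_lag1_autocorrelation(fh_fixture):
    direct, aux = fh_fixture[0], fh_fixture[1]
    m = build_model(direct, aux, link="log")
    base = dict(n_iterations=6_000, burn_in=1_000, n_chains=1, seed=4)
    unthinned = gibbs_sample(m, ChainConfig(thin_k=1, **base))
    thinned = gibbs_sample(m, ChainConfig(thin_k=5, **base))
    a1 = abs(lag1_autocorrelation(unthinned.sigma_u2[0]))
    a5 = abs(lag1_autocorrelation(thinned.sigma_u2[0]))
    assert a5 < a1


def test_shrinkage_weights_monotone_in_gamma():
    D = 5
    model = _dummy_model(D)
    chain = ChainConfig(n_iterations=100, burn_in=0, thin_k=1,
                        n_chains=1, seed=0)
    gamma = np.tile(np.array([0.001, 0.01, 0.1, 1.0, 10.0]), (1, 100, 1))
    draws = GibbsDraws(
        beta=np.zeros((1, 100, 1)),
        sigma_u2=np.full((1, 100), 0.1),
        theta=np.zeros((1, 100, D)),
        gamma=gamma,
        model=model,
        chain=chain,
    )
    w = shrinkage_weights(model, draws)["weight_on_direct"].to_numpy()
    assert (np.diff(w) < 0).all()
    assert w[2] == pytest.approx(0.5)  # gamma == sigma_u2
    assert w[0] > 0.98                 # gamma -> 0: direct dominates
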