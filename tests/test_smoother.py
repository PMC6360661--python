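import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.special import expit, logit

from childmort.gmrf import ar1_precision
from childmort.graphs import AdjacencyGraph, make_lattice_adjacency
from childmort.smoother import (MCMCConfig, ModelParams, PosteriorSurface,
                                SpaceTimeSmoother, build_precision,
                                observation_variance, summarize)
from childmort.validation import simulate_model_observations


def params(**kw):
    base = dict(alpha=-2.0, sigma2_S=0.2, rho_s=0.6, phi_t=0.7,
                tau2={m: 0.05 for m in ("direct", "cohort_MA", "cohort_TFB",
                                        "period_MA", "period_TFB")})
    base.update(kw)
    return ModelParams(**base)


# -- precision construction -------------------------------------------------

def test_single_time_point_no_spatial_dependence_is_diagonal(lattice22):
    Q = build_precision(lattice22, params(rho_s=0.0, sigma2_S=1.0), T=1)
    assert np.allclose(Q, np.diag(np.diag(Q)))
    assert np.allclose(np.diag(Q), lattice22.degrees())


def test_two_counties_reduces_to_scaled_ar1():
    # a path graph with rho_s = 0: block-diagonal, each block the AR(1)
    # precision scaled by the node degree
    g = make_lattice_adjacency(1, 2)
    Q = build_precision(g, params(rho_s=0.0, sigma2_S=1.0), T=5)
    assert np.allclose(Q[:5, :5], ar1_precision(5, 0.7))
    assert np.allclose(Q[:5, 5:], 0.0)


def test_precision_inverse_matches_dense_kronecker_oracle(lattice22):
    """Independent oracle: invert the spatial and temporal precisions
    separately, Kronecker the covariances, and compare."""
    p = params(sigma2_S=0.3, rho_s=0.7, phi_t=0.5)
    T = 3
    Q = build_precision(lattice22, p, T)
    W = lattice22.adjacency_matrix()
    sig_space = np.linalg.inv(np.diag(W.sum(1)) - 0.7 * W)
    sig_time = np.linalg.inv(ar1_precision(T, 0.5))
    oracle_cov = 0.3 * np.kron(sig_space, sig_time)
    assert np.allclose(np.linalg.inv(Q), oracle_cov, atol=1e-8)


@given(rho=st.floats(0.0, 0.999), phi=st.floats(-0.999, 0.999))
def test_precision_positive_definite_over_parameter_ranges(rho, phi):
    g = make_lattice_adjacency(2, 3)
    Q = build_precision(g, params(rho_s=rho, phi_t=phi), T=4)
    np.linalg.cholesky(Q)  # raises LinAlgError if not SPD


def test_out_of_range_parameters_rejected(lattice22):
    with pytest.raises(ValueError):
        build_precision(lattice22, params(rho_s=1.0), T=3)
    with pytest.raises(ValueError):
        build_precision(lattice22, params(phi_t=-1.0), T=3)


# -- observation variance ---------------------------------------------------

def test_observation_variance_closed_form():
    p = params(tau2={"direct": 1.0})
    assert observation_variance(np.exp(3.0), "direct", p) == pytest.approx(1 / 3)


def test_observation_variance_monotonicity():
    p1 = params(tau2={"direct": 1.0})
    p2 = params(tau2={"direct": 2.0})
    assert observation_variance(100, "direct", p2) == \
        pytest.approx(2 * observation_variance(100, "direct", p1))
    assert observation_variance(10_000, "direct", p1) < \
        observation_variance(100, "direct", p1)


def test_small_sample_size_rejected():
    with pytest.raises(ValueError, match="below minimum"):
        observation_variance(2, "direct", params(tau2={"direct": 1.0}))


# -- posterior summaries ----------------------------------------------------

def test_constant_samples_summary(lattice22):
    samples = np.full((200, 4, 2), 0.08)
    post = PosteriorSurface(samples, lattice22.node_ids, np.array([2000, 2001]))
    s = summarize(post)
    assert np.allclose(s["mean_per_1000"], 80.0)
    assert np.allclose(s["lo95"], s["hi95"])


def test_summary_matches_analytic_transform_of_normal_samples(lattice22, rng):
    z = rng.standard_normal(10_000)
    samples = expit(z)[:, None, None] * np.ones((1, 4, 1))
    post = PosteriorSurface(samples, lattice22.node_ids, np.array([2000]))
    s = summarize(post).iloc[0]
    assert s["lo95"] / 1000 == pytest.approx(expit(-1.959964), abs=0.01)
    assert s["hi95"] / 1000 == pytest.approx(expit(1.959964), abs=0.01)
    assert s["mean_per_1000"] / 1000 == pytest.approx(expit(z).mean(), abs=1e-9)


def test_mean_always_inside_interval(rng):
    samples = expit(rng.standard_normal((500, 2, 3)) - 2.0)
    g = make_lattice_adjacency(1, 2)
    post = PosteriorSurface(samples, g.node_ids, np.array([2000, 2001, 2002]))
    s = summarize(post)
    assert ((s["mean_per_1000"] >= s["lo95"]) & (s["mean_per_1000"] <= s["hi95"])).all()


def test_summarize_needs_enough_samples(lattice22):
    post = PosteriorSurface(np.full((50, 4, 1), 0.1), lattice22.node_ids,
                            np.array([2000]))
    with pytest.raises(ValueError, match="100"):
        summarize(post)


# -- MCMC -------------------------------------------------------------------

def _fixed_fit(obs, graph, start, years, seed=1, iterations=3000, burn_in=500):
    model = SpaceTimeSmoother(obs, graph, years=years)
    mcmc = MCMCConfig(iterations=iterations, burn_in=burn_in, thin=5, seed=seed)
    return model.fit(mcmc, start=start,
                     fix_params=("alpha", "sigma2_S", "rho_s", "phi_t", "tau2"))


def test_single_cell_posterior_matches_conjugate_oracle():
    """With a nearly flat field prior the posterior mean at an observed
    county-year is the precision-weighted average of its observations;
    the cell sits much nearer the large-n observation."""
    g = make_lattice_adjacency(1, 2)
    p = params(alpha=0.0, sigma2_S=1e4, rho_s=0.2, phi_t=0.0,
               tau2={"direct": 1.0})
    y1, y2 = logit(0.06), logit(0.14)
    n1, n2 = 100.0, 100_000.0
    obs = pd.DataFrame({
        "survey_id": ["a", "b"], "method": ["direct", "direct"],
        "county_id": ["c01", "c01"], "year": [2000, 2000],
        "q5": [expit(y1), expit(y2)], "n": [n1, n2]})
    res = _fixed_fit(obs, g, p, years=(2000, 2000), iterations=6000, burn_in=500)
    w1, w2 = np.log(n1), np.log(n2)
    oracle = (w1 * y1 + w2 * y2) / (w1 + w2)
    cell = logit(res.posterior.samples[:, 0, 0])
    mc_se = cell.std(ddof=1) / np.sqrt(len(cell) / 10)  # conservative ESS
    assert abs(cell.mean() - oracle) < 3 * mc_se + 0.02
    # nearer the large-n observation
    assert abs(cell.mean() - y2) < abs(cell.mean() - y1)


def test_conditional_means_match_dense_gls_oracle():
    """On a K*T = 12 instance with fixed hyper-parameters, MCMC posterior
    means of the field match the closed-form Gaussian solve."""
    p = params(alpha=-2.0, sigma2_S=0.3, rho_s=0.6, phi_t=0.7,
               tau2={m: 0.05 for m in ("direct", "cohort_MA", "cohort_TFB",
                                       "period_MA", "period_TFB")})
    obs, graph, trueQ, years = simulate_model_observations(
        p, rows=2, cols=2, T=3, n_surveys=2, seed=42)
    res = _fixed_fit(obs, graph, p, years=(years[0], years[-1]),
                     iterations=8000, burn_in=1000)
    # dense closed form: (Q_S + A' V^-1 A)^-1 A' V^-1 (y - alpha)
    K, T = 4, 3
    Q_S = build_precision(graph, p, T)
    k_idx = np.array([graph.index(c) for c in obs["county_id"]])
    t_idx = obs["year"].to_numpy() - years[0]
    cell = k_idx * T + t_idx
    v = np.array([observation_variance(n, m, p)
                  for n, m in zip(obs["n"], obs["method"])])
    y = logit(obs["q5"].to_numpy())
    P = Q_S + np.diag(np.bincount(cell, weights=1 / v, minlength=K * T))
    b = np.bincount(cell, weights=(y - p.alpha) / v, minlength=K * T)
    oracle_mean = p.alpha + np.linalg.solve(P, b)
    mcmc_mean = logit(res.posterior.samples).mean(axis=0).reshape(-1)
    sd = logit(res.posterior.samples).std(axis=0, ddof=1).reshape(-1)
    mc_se = sd / np.sqrt(res.posterior.n_samples / 10)
    assert (np.abs(mcmc_mean - oracle_mean) < 3 * mc_se + 0.01).all()


def test_zero_noise_limit_interpolates_observations():
    g = make_lattice_adjacency(2, 2)
    p = params(alpha=-2.0, sigma2_S=0.3, tau2={"direct": 1e-6})
    rng = np.random.default_rng(7)
    rows = []
    for k, c in enumerate(g.node_ids):
        for t, year in enumerate(range(2000, 2004)):
            q = float(expit(-2.0 + 0.3 * rng.standard_normal()))
            rows.append(("s0", "direct", c, year, q, 5000.0))
    obs = pd.DataFrame(rows, columns=["survey_id", "method", "county_id",
                                      "year", "q5", "n"])
    res = _fixed_fit(obs, g, p, years=(2000, 2003), iterations=2000, burn_in=200)
    post_logit = logit(res.posterior.samples).mean(axis=0)
    for _, r in obs.iterrows():
        k = g.index(r["county_id"])
        t = int(r["year"]) - 2000
        assert abs(post_logit[k, t] - logit(r["q5"])) < 1e-3


def test_fit_deterministic_under_seed():
    p = params()
    obs, graph, _, years = simulate_model_observations(p, 2, 2, 4, seed=3)
    model = SpaceTimeSmoother(obs, graph, years=(years[0], years[-1]))
    mcmc = MCMCConfig(iterations=800, burn_in=200, thin=5, seed=9)
    a = model.fit(mcmc).posterior.samples
    b = model.fit(mcmc).posterior.samples
    assert np.array_equal(a, b)


def test_unobserved_years_predicted_from_prior():
    """County-years with no data get posterior mass from the process
    prior conditioned on neighbours — wider intervals than observed cells."""
    p = params(phi_t=0.9)
    obs, graph, _, years = simulate_model_observations(p, 2, 2, 5, seed=21)
    model = SpaceTimeSmoother(obs, graph, years=(years[0] - 5, years[-1]))
    res = model.fit(MCMCConfig(iterations=2000, burn_in=500, thin=5, seed=2))
    s = res.summary_frame()
    width = s["hi95"] - s["lo95"]
    early = s["year"] < years[0]
    assert width[early].mean() > width[~early].mean()


def test_small_n_records_rejected_at_load(lattice22, caplog):
    obs = pd.DataFrame({
        "survey_id": ["a", "a"], "method": ["direct", "direct"],
        "county_id": ["c01", "c02"], "year": [2000, 2000],
        "q5": [0.1, 0.1], "n": [2.0, 100.0]})
    model = SpaceTimeSmoother(obs, lattice22)
    assert len(model.obs) == 1


def test_removing_observations_widens_interval():
    p = params()
    obs, graph, _, years = simulate_model_observations(p, 2, 2, 4, seed=5)
    model_full = SpaceTimeSmoother(obs, graph, years=(years[0], years[-1]))
    # drop all observations at one county-year
    target = (obs["county_id"] == "c01") & (obs["year"] == years[2])
    model_less = SpaceTimeSmoother(obs[~target], graph,
                                   years=(years[0], years[-1]))
    mcmc = MCMCConfig(iterations=3000, burn_in=500, thin=5, seed=4)
    wf = _width(model_full.fit(mcmc), "c01", years[2])
    wl = _width(model_less.fit(mcmc), "c01", years[2])
    assert wl > wf * 0.95  # never materially narrower without the data


def _width(res, county, year):
    s = res.summary_frame()
    row = s[(s["county_id"] == county) & (s["year"] == year)].iloc[0]
    return row["hi95"] - row["lo95"]


def test_crossval_zero_fraction_rejected():
    p = params()
    obs, graph, _, years = simulate_model_observations(p, 2, 2, 4, seed=6)
    model = SpaceTimeSmoother(obs, graph, years=(years[0], years[-1]))
    with pytest.raises(ValueError, match="holdout_fraction"):
        model.cross_validate(holdout_fraction=0.0)


def test_crossval_deterministic():
    p = params()
    obs, graph, _, years = simulate_model_observations(p, 2, 2, 5, seed=8)
    model = SpaceTimeSmoother(obs, graph, years=(years[0], years[-1]))
    mcmc = MCMCConfig(iterations=1200, burn_in=200, thin=5, seed=3)
    a = model.cross_validate(mcmc, seed=11)
    b = model.cross_validate(mcmc, seed=11)
    assert a["rmse"] == b["rmse"]
    assert a["bias"] == b["bias"]


def test_posterior_smoother_than_raw():
    """Mean absolute year-on-year change of the posterior mean does not
    exceed that of the raw per-cell estimates."""
    p = params(phi_t=0.9, sigma2_S=0.15)
    obs, graph, _, years = simulate_model_observations(p, 2, 2, 10, seed=13)
    model = SpaceTimeSmoother(obs, graph, years=(years[0], years[-1]))
    res = model.fit(MCMCConfig(iterations=2500, burn_in=500, thin=5, seed=1))
    post = res.posterior.mean()
    raw = (obs.groupby(["county_id", "year"])["q5"].mean().unstack()
           .reindex(index=graph.node_ids).to_numpy())
    rough_post = np.abs(np.diff(post, axis=1)).mean()
    rough_raw = np.abs(np.diff(raw, axis=1)).mean()
    assert rough_post <= rough_raw
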