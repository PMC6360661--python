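import numpy as np
import pytest
from scipy.special import expit, logit

from childmort.direct import direct_estimates
from childmort.gmrf import ar1_precision, car_precision
from childmort.graphs import make_lattice_adjacency
from childmort.records import records_to_frame
from childmort.simulate import (SimConfig, SurveySpec, sample_true_surface,
                                simulate_survey)


def _config(graph, **kw):
    defaults = dict(K=graph.n_nodes, year_range=(1990, 2009),
                    surveys=(SurveySpec(year=2009, counties=graph.node_ids,
                                        women_per_county=50),),
                    seed=11)
    defaults.update(kw)
    return SimConfig(**defaults)


def test_zero_process_variance_gives_constant_surface(lattice22):
    cfg = _config(lattice22, sigma2_S=0.0, alpha=-1.5)
    surf = sample_true_surface(cfg, lattice22)
    assert np.allclose(surf.Q, expit(-1.5))
    assert np.allclose(surf.S, 0.0)


def test_phi_zero_gives_uncorrelated_years(lattice22):
    lags = []
    for seed in range(400):
        cfg = _config(lattice22, phi_t=0.0, sigma2_S=1.0, seed=seed)
        surf = sample_true_surface(cfg, lattice22)
        s = surf.S
        lags.append(np.mean(s[:, :-1] * s[:, 1:]) / np.mean(s ** 2))
    # empirical lag-1 correlation ~ 0 within Monte-Carlo error
    assert abs(np.mean(lags)) < 3.0 / np.sqrt(len(lags))


def test_empirical_covariance_matches_kronecker_oracle(lattice22):
    """Dense-oracle check of the separable covariance: assemble
    Sigma_space (x) Sigma_time by explicit inversion and Kronecker
    product, then compare with the empirical covariance of many draws."""
    K, T, n_draws = 4, 3, 3000
    cfg = _config(lattice22, year_range=(2000, 2002), sigma2_S=0.5,
                  rho_s=0.8, phi_t=0.6)
    draws = np.empty((n_draws, K * T))
    for d in range(n_draws):
        cfg.seed = d
        draws[d] = sample_true_surface(cfg, lattice22).S.reshape(-1)
    emp = np.cov(draws, rowvar=False)

    sig_s = np.linalg.inv(car_precision(lattice22, 0.8))
    sig_t = np.linalg.inv(ar1_precision(T, 0.6))
    oracle = np.kron(sig_s, sig_t)
    oracle *= 0.5 / np.outer(np.diag(sig_s), np.diag(sig_t)).mean()

    frob = np.linalg.norm(emp - oracle) / np.linalg.norm(oracle)
    assert frob < 0.12, f"relative Frobenius distance {frob:.3f}"
    # distance shrinks as the number of replicates grows
    emp_small = np.cov(draws[:300], rowvar=False)
    frob_small = np.linalg.norm(emp_small - oracle) / np.linalg.norm(oracle)
    assert frob < frob_small


def test_invalid_dependence_parameters_rejected(lattice22):
    cfg = _config(lattice22, rho_s=1.0)
    with pytest.raises(ValueError, match="rho_s"):
        sample_true_surface(cfg, lattice22)
    cfg = _config(lattice22, phi_t=1.0)
    with pytest.raises(ValueError, match="phi_t"):
        sample_true_surface(cfg, lattice22)


def test_zero_mortality_surface_produces_no_deaths(lattice22):
    cfg = _config(lattice22, alpha=-40.0, sigma2_S=0.0)
    surf = sample_true_surface(cfg, lattice22)
    records = simulate_survey(cfg, surf, 0)
    assert all(c.death_age_months is None
               for w in records for c in w.children)


def test_same_seed_reproduces_identical_records(lattice22):
    cfg = _config(lattice22)
    surf = sample_true_surface(cfg, lattice22)
    a = simulate_survey(cfg, surf, 0)
    b = simulate_survey(cfg, surf, 0)
    assert a == b


def test_survey_index_out_of_range(lattice22):
    cfg = _config(lattice22)
    surf = sample_true_surface(cfg, lattice22)
    with pytest.raises(IndexError):
        simulate_survey(cfg, surf, 5)


def test_direct_estimator_recovers_constant_truth():
    """Large-sample consistency: with a flat true q5 of 0.10 the direct
    estimator on fully observed periods matches within binomial error."""
    graph = make_lattice_adjacency(1, 2)
    q_true = 0.10
    cfg = SimConfig(K=2, year_range=(1970, 2010), alpha=float(logit(q_true)),
                    sigma2_S=0.0,
                    surveys=(SurveySpec(year=2010, counties=("c01",),
                                        women_per_county=12_000),),
                    seed=5)
    surf = sample_true_surface(cfg, graph)
    records = simulate_survey(cfg, surf, 0)
    frame = records_to_frame(records)
    est = direct_estimates(frame, by_county=False)
    # periods ending >= 5 years before interview have complete exposure
    old = est[est["year"] <= 2004]
    n_children = est["n_children"].iloc[0]
    pooled = old["q5"].mean()
    tol = 3.0 * np.sqrt(q_true * (1 - q_true) / n_children)
    assert abs(pooled - q_true) < tol, f"{pooled:.4f} vs {q_true} (tol {tol:.4f})"


def test_women_ages_and_child_ordering(lattice22):
    cfg = _config(lattice22)
    surf = sample_true_surface(cfg, lattice22)
    for w in simulate_survey(cfg, surf, 0):
        assert 15 <= w.age_years <= 49
        for c in w.children:
            assert c.birth_month <= w.interview_month
            if c.death_age_months is not None:
                assert c.birth_month + c.death_age_months <= w.interview_month
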