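"""Simulation studies used to validate the estimation chain.

These routines generate data with known ground truth and measure how well
each stage recovers it: held-out accuracy of the calibrated indirect
conversions, posterior recovery/coverage of the smoother on model-simulated
data, and hold-out cross-validation bias.  They are part of the package
(not test scaffolding) so the same experiments can be rerun from the
command line or scripts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .direct import direct_estimates
from .graphs import make_lattice_adjacency
from .indirect import (calibrate_coefficients, cohort_q5, parity_ratios,
                       period_q5, period_redistribute)
from .records import aggregate_sbh, records_to_frame
from .simulate import SimConfig, SurveySpec, sample_true_surface, simulate_survey
from .smoother import (MCMCConfig, ModelParams, SpaceTimeSmoother,
                       build_precision)


def make_calibration_corpus(n_surveys: int, women_per_survey: int = 1500,
                            seed: int = 0, q5_range: tuple = (0.04, 0.25)):
    """Synthetic survey corpus with varied true mortality levels.

    Each survey is a two-county population with its own intercept drawn so
    true q5 spans ``q5_range``, mild spatio-temporal variation, and full
    complete birth histories.  Returns (corpus, truths): the list of
    record lists and each survey's true surface.
    """
    rng = np.random.default_rng(int(seed) % (2 ** 31))
    graph = make_lattice_adjacency(1, 2)
    corpus, truths = [], []
    lo, hi = logit(q5_range[0]), logit(q5_range[1])
    for s in range(n_surveys):
        alpha = float(rng.uniform(lo, hi))
        year = int(rng.integers(1995, 2014))
        config = SimConfig(
            K=2, year_range=(year - 40, year), alpha=alpha,
            sigma2_S=0.01, rho_s=0.5, phi_t=0.95,
            surveys=(SurveySpec(year=year, counties=graph.node_ids,
                                women_per_county=women_per_survey // 2),),
            seed=int(rng.integers(2 ** 31)))
        surface = sample_true_surface(config, graph)
        corpus.append(simulate_survey(config, surface, 0))
        truths.append(surface)
    return corpus, truths


def calibration_holdout_study(n_train: int = 30, n_test: int = 8,
                              women_per_survey: int = 5000, seed: int = 0,
                              grouping: str = "MA") -> dict:
    """Calibrate on a training corpus, predict held-out surveys.

    For each held-out survey the cohort and period conversions are applied
    to its summary birth histories and compared with the direct estimator
    on the same population at the matching reference times.  Reports the
    median absolute relative error over the central cohorts (20-34) and
    recent period years (0-15), where the conversions are best determined.
    """
    train, _ = make_calibration_corpus(n_train, women_per_survey, seed=seed)
    test, _ = make_calibration_corpus(n_test, women_per_survey, seed=seed + 1)
    cohort, period, dist = calibrate_coefficients(train, grouping=grouping)

    central_groups = {"20-24", "25-29", "30-34"}
    cohort_err, period_err = [], []
    for records in test:
        frame = records_to_frame(records)
        direct = direct_estimates(frame, by_county=False)
        sbh = aggregate_sbh(records, grouping=grouping)
        sbh_ma = sbh if grouping == "MA" else aggregate_sbh(records, "MA")
        ratios = parity_ratios(sbh_ma)
        for q5, ref_year, g in cohort_q5(sbh, cohort, ratios):
            if g not in central_groups:
                continue
            truth = _truth_at(direct, ref_year)
            if truth is not None:
                cohort_err.append(abs(q5 - truth) / truth)
        per_year = period_redistribute(sbh, dist)
        for q5, year in period_q5(per_year, period, sbh.interview_year):
            t = sbh.interview_year - year
            if not 0 <= t <= 15:
                continue
            truth = _truth_at(direct, year)
            if truth is not None:
                period_err.append(abs(q5 - truth) / truth)
    return {
        "cohort_median_rel_err": float(np.median(cohort_err)),
        "period_median_rel_err": float(np.median(period_err)),
        "n_cohort": len(cohort_err), "n_period": len(period_err),
        "coefficients": (cohort, period, dist)}


def _truth_at(direct: pd.DataFrame, year: float, max_gap: float = 1.5):
    if direct.empty:
        return None
    gaps = (direct["year"] - year).abs()
    i = gaps.idxmin()
    if gaps.loc[i] > max_gap:
        return None
    q = direct.loc[i, "q5"]
    return float(q) if 0 < q < 1 else None


def simulate_model_observations(params: ModelParams, rows: int = 3,
                                cols: int = 3, T: int = 20,
                                n_surveys: int = 2, seed: int = 0):
    """Observations drawn exactly from the smoothing model.

    Every (survey, method) stratum observes all county-years with
    log-uniform sample sizes in [1e2, 1e5]; noise follows the
    tau2_j / log(n) heteroscedastic law.  Returns (obs frame, graph,
    true Q surface (K, T), years).
    """
    rng = np.random.default_rng(int(seed) % (2 ** 31))
    graph = make_lattice_adjacency(rows, cols)
    K = graph.n_nodes
    years = np.arange(2000, 2000 + T)
    Q_prec = build_precision(graph, params, T)
    L = np.linalg.cholesky(Q_prec)
    s_vec = np.linalg.solve(L.T, rng.standard_normal(K * T))
    S = s_vec.reshape(K, T)
    trueQ = expit(params.alpha + S)
    rows_out = []
    for sid in range(n_surveys):
        for method, tau2 in params.tau2.items():
            n = 10 ** rng.uniform(2, 5, size=K * T)
            noise_sd = np.sqrt(tau2 / np.log(n))
            y = params.alpha + s_vec + noise_sd * rng.standard_normal(K * T)
            q5 = expit(y)
            for c in range(K * T):
                k, t = divmod(c, T)
                rows_out.append((f"s{sid}", method, graph.node_ids[k],
                                 int(years[t]), q5[c], n[c]))
    obs = pd.DataFrame(rows_out, columns=["survey_id", "method", "county_id",
                                          "year", "q5", "n"])
    return obs, graph, trueQ, years


def smoother_recovery_study(n_replicates: int = 20, rows: int = 3,
                            cols: int = 3, T: int = 20,
                            mcmc: MCMCConfig | None = None,
                            seed: int = 0) -> dict:
    """Posterior recovery and interval coverage on model-simulated data.

    Per replicate: simulate from the model, fit, and record the RMSE of
    the posterior mean against the true surface (probability scale), the
    RMSE of the raw per-observation estimates against the same truth, and
    the fraction of county-years whose 95% credible interval covers the
    truth.  Pooled over replicates.
    """
    mcmc = mcmc or MCMCConfig(iterations=11_000, burn_in=1_000, thin=10)
    params = ModelParams(alpha=-2.2, sigma2_S=0.15, rho_s=0.9, phi_t=0.9,
                         tau2={m: t for m, t in zip(
                             ("direct", "cohort_MA", "cohort_TFB",
                              "period_MA", "period_TFB"),
                             (0.05, 0.10, 0.10, 0.08, 0.08))})
    rmse_post, rmse_raw, covered, total = [], [], 0, 0
    for r in range(n_replicates):
        obs, graph, trueQ, years = simulate_model_observations(
            params, rows, cols, T, seed=seed + 1000 * r)
        model = SpaceTimeSmoother(obs, graph, years=(years[0], years[-1]))
        mc = MCMCConfig(iterations=mcmc.iterations, burn_in=mcmc.burn_in,
                        thin=mcmc.thin, seed=seed + 1000 * r + 7)
        res = model.fit(mc)
        post = res.posterior.samples
        post_mean = post.mean(axis=0)
        rmse_post.append(float(np.sqrt(np.mean((post_mean - trueQ) ** 2))))
        k_idx = np.array([graph.index(c) for c in obs["county_id"]])
        t_idx = obs["year"].to_numpy() - years[0]
        raw_err = obs["q5"].to_numpy() - trueQ[k_idx, t_idx]
        rmse_raw.append(float(np.sqrt(np.mean(raw_err ** 2))))
        lo = np.percentile(post, 2.5, axis=0)
        hi = np.percentile(post, 97.5, axis=0)
        covered += int(((trueQ >= lo) & (trueQ <= hi)).sum())
        total += trueQ.size
    return {"rmse_posterior": float(np.mean(rmse_post)),
            "rmse_raw": float(np.mean(rmse_raw)),
            "coverage": covered / total,
            "n_replicates": n_replicates,
            "n_cells": total}


def crossval_bias_study(n_replicates: int = 3, rows: int = 3, cols: int = 3,
                        T: int = 20, mcmc: MCMCConfig | None = None,
                        holdout_fraction: float = 0.10, seed: int = 0) -> dict:
    """Hold-out cross-validation on well-specified simulations.

    Pools held-out prediction errors over replicates and reports the bias
    with its Monte-Carlo standard error; under a well-specified model the
    bias should be statistically indistinguishable from zero.
    """
    mcmc = mcmc or MCMCConfig(iterations=6_000, burn_in=1_000, thin=5)
    params = ModelParams(alpha=-2.2, sigma2_S=0.15, rho_s=0.9, phi_t=0.9,
                         tau2={m: 0.08 for m in ("direct", "cohort_MA",
                                                 "cohort_TFB", "period_MA",
                                                 "period_TFB")})
    errors = []
    rmses = []
    for r in range(n_replicates):
        obs, graph, trueQ, years = simulate_model_observations(
            params, rows, cols, T, seed=seed + 31 * r)
        model = SpaceTimeSmoother(obs, graph, years=(years[0], years[-1]))
        mc = MCMCConfig(iterations=mcmc.iterations, burn_in=mcmc.burn_in,
                        thin=mcmc.thin, seed=seed + 31 * r + 3)
        cv = model.cross_validate(mc, holdout_fraction=holdout_fraction,
                                  seed=seed + 31 * r + 5)
        errors.append(cv["detail"]["error"].to_numpy())
        rmses.append(cv["rmse"])
    errors = np.concatenate(errors)
    return {"bias": float(errors.mean()),
            "bias_mc_se": float(errors.std(ddof=1) / np.sqrt(errors.size)),
            "rmse": float(np.mean(rmses)),
            "n_heldout": int(errors.size)}
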