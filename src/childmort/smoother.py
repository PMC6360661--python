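"""Bayesian spatio-temporal smoothing of under-five mortality estimates.

Every survey x demographic-method combination yields noisy county-year
estimates of the same quantity, the probability q5 of dying before age
five.  The smoother fuses them through the hierarchical model

    logit(Q_ijkt) = alpha + S_kt + Z_ijkt

where i indexes the survey, j the demographic method, k the county and t
the year.  S is a zero-mean Gaussian field with separable precision

    Q_S = (1 / sigma2_S) * (D - rho_s W) (x) Q_AR1(phi_t)

(proper CAR in space, stationary AR(1) in time), and Z is heteroscedastic
Gaussian noise with Var(Z_ijkt) = tau2_j / log(n_ijkt): observations are
weighted by the log of their sample size, so censuses inform but never
dominate, while tau2_j absorbs the excess variability of each demographic
method.

Inference is MCMC: the Gaussian field and intercept are updated by Gibbs
steps (their full conditionals are Gaussian), the hyper-parameters by
adaptive random-walk Metropolis on transformed scales.  County-years with
no data are predicted from the process prior conditioned on their
neighbours — the field is sampled jointly, so this happens automatically
and without an observation noise term.

The public surface follows the Model/Results convention: build a
:class:`SpaceTimeSmoother` from an observation table and an adjacency
graph, call :meth:`~SpaceTimeSmoother.fit`, and read the posterior off the
returned :class:`SmootherResults`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .gmrf import ar1_precision, car_precision, kron_quadform
from .graphs import AdjacencyGraph

logger = logging.getLogger(__name__)

METHODS = ("direct", "cohort_MA", "cohort_TFB", "period_MA", "period_TFB")

MIN_SAMPLE_SIZE = 3  # so log(n) > 1 and the noise variance stays bounded


@dataclass
class ModelParams:
    """Hyper-parameters of the smoothing model."""

    alpha: float = -2.0
    sigma2_S: float = 0.1
    rho_s: float = 0.5
    phi_t: float = 0.8
    tau2: dict = field(default_factory=lambda: {m: 0.05 for m in METHODS})

    def validate(self):
        if self.sigma2_S <= 0:
            raise ValueError("sigma2_S must be positive")
        if not 0.0 <= self.rho_s < 1.0:
            raise ValueError("rho_s must be in [0, 1)")
        if not -1.0 < self.phi_t < 1.0:
            raise ValueError("phi_t must be in (-1, 1)")
        if any(v <= 0 for v in self.tau2.values()):
            raise ValueError("tau2 factors must be positive")
        return self


@dataclass
class Priors:
    """Weakly informative defaults; overridable per fit."""

    alpha_sd: float = 10.0
    sigma_S_halfnormal_sd: float = 5.0  # on the SD scale
    tau_halfnormal_sd: float = 5.0      # on the SD scale


@dataclass
class MCMCConfig:
    iterations: int = 110_000
    burn_in: int = 10_000
    thin: int = 10
    seed: int = 0
    proposal_scales: dict = field(default_factory=lambda: {
        "sigma2_S": 0.3, "rho_s": 0.5, "phi_t": 0.4, "tau2": 0.3})

    @property
    def n_retained(self) -> int:
        return (self.iterations - self.burn_in) // self.thin

    def __post_init__(self):
        if self.burn_in >= self.iterations:
            raise ValueError("burn_in must be smaller than iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


def build_precision(graph: AdjacencyGraph, params: ModelParams, T: int) -> np.ndarray:
    """Joint precision of vec(S) (cell order k*T + t):
    (1/sigma2_S) * (D - rho_s W) (x) Q_AR1(phi_t); symmetric positive
    definite over the valid parameter ranges."""
    params.validate()
    Qs = car_precision(graph, params.rho_s)
    Qt = ar1_precision(T, params.phi_t)
    return np.kron(Qs, Qt) / params.sigma2_S


def observation_variance(n: float, method: str, params: ModelParams,
                         mode: str = "divide") -> float:
    """Noise variance of one observation: tau2_j / log(n).

    Weights are proportional to log n, so a census with n ~ 1e6 carries
    only a few times the weight of a survey with n ~ 1e3.  ``mode``
    "multiply" gives the literal product tau2_j * log(n) reading instead.
    """
    n = float(n)
    if n < MIN_SAMPLE_SIZE:
        raise ValueError(f"sample size {n} below minimum {MIN_SAMPLE_SIZE}")
    tau2 = params.tau2[method]
    if mode == "divide":
        return tau2 / np.log(n)
    if mode == "multiply":
        return tau2 * np.log(n)
    raise ValueError(f"unknown variance mode {mode!r}")


@dataclass
class PosteriorSurface:
    """Retained posterior draws of the U5M surface on the probability
    scale, shape (n_samples, K, T)."""

    samples: np.ndarray
    county_ids: tuple
    years: np.ndarray

    def __post_init__(self):
        s = self.samples
        if not ((s > 0) & (s < 1)).all():
            raise ValueError("posterior samples must lie in (0, 1)")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    def mean(self) -> np.ndarray:
        return self.samples.mean(axis=0)


def summarize(posterior: PosteriorSurface) -> pd.DataFrame:
    """Per county-year posterior mean and 95% credible interval, on the
    deaths-per-1000-live-births scale."""
    if posterior.n_samples < 100:
        raise ValueError("need at least 100 retained samples to summarize")
    mean = posterior.samples.mean(axis=0) * 1000.0
    lo = np.percentile(posterior.samples, 2.5, axis=0) * 1000.0
    hi = np.percentile(posterior.samples, 97.5, axis=0) * 1000.0
    rows = []
    for k, county in enumerate(posterior.county_ids):
        for t, year in enumerate(posterior.years):
            rows.append((county, int(year), mean[k, t], lo[k, t], hi[k, t]))
    return pd.DataFrame(rows, columns=["county_id", "year", "mean_per_1000",
                                       "lo95", "hi95"])


class SpaceTimeSmoother:
    """Model object for the spatio-temporal smoothing of q5 estimates.

    Parameters
    ----------
    observations : DataFrame
        Columns ``survey_id, method, county_id, year, q5, n``; q5 strictly
        inside (0, 1), method one of {direct, cohort_MA, cohort_TFB,
        period_MA, period_TFB}, n >= 3 (smaller records are rejected at
        load with a log entry).
    graph : AdjacencyGraph
        County contiguity; every observation's county must be a node.
    years : (int, int), optional
        Inclusive prediction span; defaults to the observed span.  Years
        with no data anywhere are predicted from the process prior.
    """

    def __init__(self, observations: pd.DataFrame, graph: AdjacencyGraph,
                 years: tuple | None = None, priors: Priors | None = None,
                 variance_mode: str = "divide"):
        obs = observations.copy().reset_index(drop=True)
        required = {"survey_id", "method", "county_id", "year", "q5", "n"}
        missing = required - set(obs.columns)
        if missing:
            raise ValueError(f"observation table missing columns {sorted(missing)}")
        bad_method = ~obs["method"].isin(METHODS)
        if bad_method.any():
            raise ValueError(f"unknown method(s) {sorted(obs['method'][bad_method].unique())}")
        small = obs["n"] < MIN_SAMPLE_SIZE
        if small.any():
            logger.warning("rejecting %d observation(s) with n < %d at load",
                           int(small.sum()), MIN_SAMPLE_SIZE)
            obs = obs[~small].reset_index(drop=True)
        if obs.empty:
            raise ValueError("no usable observations")
        if not ((obs["q5"] > 0) & (obs["q5"] < 1)).all():
            raise ValueError("q5 must lie strictly in (0, 1)")
        unknown = set(obs["county_id"].astype(str)) - set(graph.node_ids)
        if unknown:
            raise ValueError(f"observations reference unknown counties {sorted(unknown)}")
        self.graph = graph
        self.priors = priors or Priors()
        self.variance_mode = variance_mode
        if years is None:
            years = (int(obs["year"].min()), int(obs["year"].max()))
        self.years = np.arange(years[0], years[1] + 1)
        out_of_span = ~obs["year"].between(years[0], years[1])
        if out_of_span.any():
            raise ValueError(f"{int(out_of_span.sum())} observation(s) outside "
                             f"the prediction span {years}")
        self.obs = obs
        self.K = graph.n_nodes
        self.T = len(self.years)
        k_idx = np.array([graph.index(c) for c in obs["county_id"].astype(str)])
        t_idx = obs["year"].to_numpy(dtype=int) - years[0]
        self._cell = k_idx * self.T + t_idx
        self._y = logit(obs["q5"].to_numpy(dtype=float))
        self._logn = np.log(obs["n"].to_numpy(dtype=float))
        self._method = obs["method"].to_numpy()

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, graph: AdjacencyGraph,
                       **kwargs) -> "SpaceTimeSmoother":
        return cls(frame, graph, **kwargs)

    # -- likelihood pieces -------------------------------------------------

    def _obs_variances(self, params: ModelParams) -> np.ndarray:
        tau2 = np.array([params.tau2[m] for m in self._method])
        if self.variance_mode == "divide":
            return tau2 / self._logn
        return tau2 * self._logn

    def _field_logpdf(self, X: np.ndarray, params: ModelParams,
                      Qs: np.ndarray, Qt: np.ndarray) -> float:
        """log N(vec(X); 0, Q_S^{-1}) up to a constant."""
        K, T = self.K, self.T
        sign_s, logdet_s = np.linalg.slogdet(Qs)
        sign_t, logdet_t = np.linalg.slogdet(Qt)
        if sign_s <= 0 or sign_t <= 0:
            return -np.inf
        logdet = T * logdet_s + K * logdet_t - K * T * np.log(params.sigma2_S)
        qf = kron_quadform(Qs, Qt, X) / params.sigma2_S
        return 0.5 * logdet - 0.5 * qf

    # -- fitting -----------------------------------------------------------

    def fit(self, mcmc: MCMCConfig | None = None,
            start: ModelParams | None = None,
            fix_params: tuple = ()) -> "SmootherResults":
        """Run the MCMC and return a results object.

        ``fix_params`` names hyper-parameters ("alpha", "sigma2_S",
        "rho_s", "phi_t", "tau2") to hold at their starting values — used
        for conditional-posterior checks against closed-form solutions.
        """
        mcmc = mcmc or MCMCConfig()
        components = self._components()
        if len(components) > 1:
            warnings.warn("adjacency graph is disconnected; fitting each "
                          "component separately", stacklevel=2)
            return self._fit_components(components, mcmc, start, fix_params)
        return self._fit_single(mcmc, start, fix_params)

    def _components(self):
        import networkx as nx
        return [tuple(sorted(c)) for c in
                nx.connected_components(self.graph.to_networkx())]

    def _fit_components(self, components, mcmc, start, fix_params):
        partial = []
        for nodes in components:
            if len(nodes) < 2:
                raise ValueError("cannot fit an isolated single-county component")
            sub_edges = frozenset(e for e in self.graph.edges
                                  if e[0] in nodes and e[1] in nodes)
            sub_graph = AdjacencyGraph(tuple(nodes), sub_edges)
            sub_obs = self.obs[self.obs["county_id"].isin(nodes)]
            sub = SpaceTimeSmoother(sub_obs, sub_graph,
                                    years=(self.years[0], self.years[-1]),
                                    priors=self.priors,
                                    variance_mode=self.variance_mode)
            partial.append(sub._fit_single(mcmc, start, fix_params))
        samples = np.concatenate([r.posterior.samples for r in partial], axis=1)
        county_ids = tuple(c for r in partial for c in r.posterior.county_ids)
        # reorder to the original graph's node order
        pos = {c: i for i, c in enumerate(county_ids)}
        perm = [pos[c] for c in self.graph.node_ids]
        posterior = PosteriorSurface(samples[:, perm, :], self.graph.node_ids,
                                     self.years)
        traces = partial[0].traces
        return SmootherResults(self, posterior, traces, partial[0].acceptance)

    def _fit_single(self, mcmc, start, fix_params):
        rng = np.random.default_rng(int(mcmc.seed) % (2 ** 31))
        K, T = self.K, self.T
        params = replace(start) if start is not None else ModelParams()
        params.tau2 = dict(params.tau2)
        params.validate()
        pri = self.priors
        y, cell, logn = self._y, self._cell, self._logn
        n_cells = K * T

        # per-cell observation tallies are recomputed when tau2 changes
        methods_present = [m for m in METHODS if (self._method == m).any()]
        method_rows = {m: np.flatnonzero(self._method == m) for m in methods_present}

        X = np.zeros((K, T))
        alpha = params.alpha
        scales = {k: float(v) for k, v in mcmc.proposal_scales.items()}
        tau_scales = {m: scales["tau2"] for m in methods_present}
        acc = {k: [0, 0] for k in ("sigma2_S", "rho_s", "phi_t")}
        acc_tau = {m: [0, 0] for m in methods_present}

        Qs = car_precision(self.graph, params.rho_s)
        Qt = ar1_precision(T, params.phi_t)

        n_keep = mcmc.n_retained
        kept = np.empty((n_keep, K, T))
        trace_rows = []
        keep_i = 0

        def obs_var():
            return self._obs_variances(params)

        v = obs_var()
        if not np.isfinite(self._field_logpdf(X, params, Qs, Qt)):
            raise RuntimeError(f"non-finite posterior at initialization: {params}")

        for it in range(mcmc.iterations):
            # --- Gibbs: latent field S --------------------------------
            w = np.bincount(cell, weights=1.0 / v, minlength=n_cells)
            b = np.bincount(cell, weights=(y - alpha) / v, minlength=n_cells)
            P = np.kron(Qs, Qt) / params.sigma2_S
            P[np.diag_indices_from(P)] += w
            L = np.linalg.cholesky(P)
            mu = np.linalg.solve(L.T, np.linalg.solve(L, b))
            s_vec = mu + np.linalg.solve(L.T, rng.standard_normal(n_cells))
            X = s_vec.reshape(K, T)

            # --- Gibbs: intercept alpha -------------------------------
            if "alpha" not in fix_params:
                resid = y - s_vec[cell]
                prec = 1.0 / pri.alpha_sd ** 2 + np.sum(1.0 / v)
                mean = np.sum(resid / v) / prec
                alpha = mean + rng.standard_normal() / np.sqrt(prec)
                params.alpha = alpha

            # --- MH: sigma2_S (log scale, conjugate-ish random walk) --
            if "sigma2_S" not in fix_params:
                cur = params.sigma2_S
                prop = cur * np.exp(scales["sigma2_S"] * rng.standard_normal())
                qf = kron_quadform(Qs, Qt, X)
                def sig_lp(s2):
                    # field likelihood terms in sigma2 + half-normal prior on
                    # the SD scale (density in s2 gains a s2^{-1/2} factor)
                    return (-0.5 * n_cells * np.log(s2) - 0.5 * qf / s2
                            - 0.5 * s2 / pri.sigma_S_halfnormal_sd ** 2
                            - 0.5 * np.log(s2)
                            + np.log(s2))  # Jacobian of log transform
                lr = sig_lp(prop) - sig_lp(cur)
                acc["sigma2_S"][1] += 1
                if np.log(rng.random()) < lr:
                    params.sigma2_S = prop
                    acc["sigma2_S"][0] += 1

            # --- MH: rho_s (logit scale) ------------------------------
            if "rho_s" not in fix_params:
                cur = params.rho_s
                z = logit(np.clip(cur, 1e-12, 1 - 1e-12))
                zp = z + scales["rho_s"] * rng.standard_normal()
                prop = float(expit(zp))
                Qs_prop = car_precision(self.graph, prop)
                lp_cur = self._field_logpdf(X, params, Qs, Qt) + np.log(cur * (1 - cur))
                lp_prop = self._field_logpdf(X, params, Qs_prop, Qt) + np.log(prop * (1 - prop))
                acc["rho_s"][1] += 1
                if np.log(rng.random()) < lp_prop - lp_cur:
                    params.rho_s = prop
                    Qs = Qs_prop
                    acc["rho_s"][0] += 1

            # --- MH: phi_t (atanh scale) ------------------------------
            if "phi_t" not in fix_params:
                cur = params.phi_t
                z = np.arctanh(cur)
                zp = z + scales["phi_t"] * rng.standard_normal()
                prop = float(np.tanh(zp))
                Qt_prop = ar1_precision(T, prop)
                lp_cur = self._field_logpdf(X, params, Qs, Qt) + np.log(1 - cur ** 2)
                lp_prop = self._field_logpdf(X, params, Qs, Qt_prop) + np.log(1 - prop ** 2)
                acc["phi_t"][1] += 1
                if np.log(rng.random()) < lp_prop - lp_cur:
                    params.phi_t = prop
                    Qt = Qt_prop
                    acc["phi_t"][0] += 1

            # --- MH: tau2 per method (log scale) ----------------------
            if "tau2" not in fix_params:
                resid = y - alpha - s_vec[cell]
                for m in methods_present:
                    rowsm = method_rows[m]
                    cur = params.tau2[m]
                    prop = cur * np.exp(tau_scales[m] * rng.standard_normal())
                    ln = logn[rowsm]
                    r2 = resid[rowsm] ** 2
                    if self.variance_mode == "divide":
                        def tau_lp(t2):
                            vv = t2 / ln
                            return (-0.5 * np.sum(np.log(vv)) - 0.5 * np.sum(r2 / vv)
                                    - 0.5 * t2 / pri.tau_halfnormal_sd ** 2
                                    - 0.5 * np.log(t2) + np.log(t2))
                    else:
                        def tau_lp(t2):
                            vv = t2 * ln
                            return (-0.5 * np.sum(np.log(vv)) - 0.5 * np.sum(r2 / vv)
                                    - 0.5 * t2 / pri.tau_halfnormal_sd ** 2
                                    - 0.5 * np.log(t2) + np.log(t2))
                    acc_tau[m][1] += 1
                    if np.log(rng.random()) < tau_lp(prop) - tau_lp(cur):
                        params.tau2[m] = prop
                        acc_tau[m][0] += 1
                v = obs_var()

            # --- adapt proposal scales during burn-in -----------------
            if it < mcmc.burn_in and (it + 1) % 100 == 0:
                for k in acc:
                    a, nn = acc[k]
                    if nn:
                        rate = a / nn
                        scales[k] *= np.exp(0.5 * (rate - 0.3))
                        acc[k] = [0, 0]
                for m in acc_tau:
                    a, nn = acc_tau[m]
                    if nn:
                        rate = a / nn
                        tau_scales[m] *= np.exp(0.5 * (rate - 0.3))
                        acc_tau[m] = [0, 0]

            # --- retain -----------------------------------------------
            if it >= mcmc.burn_in and (it - mcmc.burn_in) % mcmc.thin == 0:
                if keep_i < n_keep:
                    # clamp away from exact 0/1 (float saturation of expit
                    # for extreme logits under near-flat priors)
                    kept[keep_i] = np.clip(expit(alpha + X),
                                           5e-324, 1.0 - 2.0 ** -53)
                    keep_i += 1
                    trace_rows.append((params.alpha, params.sigma2_S,
                                       params.rho_s, params.phi_t,
                                       *[params.tau2[m] for m in methods_present]))

        posterior = PosteriorSurface(kept[:keep_i], self.graph.node_ids, self.years)
        traces = pd.DataFrame(trace_rows, columns=[
            "alpha", "sigma2_S", "rho_s", "phi_t",
            *[f"tau2_{m}" for m in methods_present]])
        acceptance = {k: (a / nn if nn else np.nan) for k, (a, nn) in acc.items()}
        for m, (a, nn) in acc_tau.items():
            acceptance[f"tau2_{m}"] = a / nn if nn else np.nan
        return SmootherResults(self, posterior, traces, acceptance)

    # -- cross-validation --------------------------------------------------

    def cross_validate(self, mcmc: MCMCConfig | None = None,
                       holdout_fraction: float = 0.10,
                       seed: int = 0) -> dict:
        """Per-stratum hold-out validation.

        Within every (survey, method) stratum with at least 10
        observations, ``holdout_fraction`` of records are held out; the
        model is refitted on the rest and the held-out q5 predicted on the
        probability scale.  Returns a dict with ``rmse``, ``bias``,
        ``n_heldout`` and a ``detail`` frame of predictions.
        """
        if holdout_fraction <= 0 or holdout_fraction >= 1:
            raise ValueError("holdout_fraction must be in (0, 1)")
        rng = np.random.default_rng(int(seed) % (2 ** 31))
        held = []
        for (sid, m), idx in self.obs.groupby(["survey_id", "method"]).groups.items():
            idx = np.asarray(idx)
            if len(idx) < 10:
                warnings.warn(f"stratum ({sid}, {m}) has {len(idx)} < 10 "
                              "observations; skipped from hold-out", stacklevel=2)
                continue
            n_hold = max(1, int(round(holdout_fraction * len(idx))))
            held.append(rng.choice(idx, size=n_hold, replace=False))
        if not held:
            raise ValueError("no stratum large enough to hold out from")
        held = np.concatenate(held)
        train = self.obs.drop(index=held)
        test = self.obs.loc[held]
        sub = SpaceTimeSmoother(train, self.graph,
                                years=(self.years[0], self.years[-1]),
                                priors=self.priors,
                                variance_mode=self.variance_mode)
        res = sub.fit(mcmc)
        mean_surface = res.posterior.mean()
        k_idx = np.array([self.graph.index(c) for c in test["county_id"].astype(str)])
        t_idx = test["year"].to_numpy(dtype=int) - self.years[0]
        pred = mean_surface[k_idx, t_idx]
        err = pred - test["q5"].to_numpy(dtype=float)
        detail = test.assign(predicted=pred, error=err)
        return {"rmse": float(np.sqrt(np.mean(err ** 2))),
                "bias": float(np.mean(err)),
                "n_heldout": int(len(err)),
                "detail": detail}


class SmootherResults:
    """Posterior surface, hyper-parameter traces and diagnostics."""

    def __init__(self, model: SpaceTimeSmoother, posterior: PosteriorSurface,
                 traces: pd.DataFrame, acceptance: dict):
        self.model = model
        self.posterior = posterior
        self.traces = traces
        self.acceptance = acceptance

    def summary_frame(self) -> pd.DataFrame:
        """Per county-year posterior mean and 95% CI per 1000 live births."""
        return summarize(self.posterior)

    def params_summary(self) -> pd.DataFrame:
        q = self.traces.quantile([0.025, 0.5, 0.975])
        out = pd.DataFrame({
            "mean": self.traces.mean(), "sd": self.traces.std(),
            "q2.5": q.loc[0.025], "median": q.loc[0.5], "q97.5": q.loc[0.975]})
        out["acceptance"] = [self.acceptance.get(p, np.nan) for p in out.index]
        return out

    def summary(self) -> str:
        lines = ["Spatio-temporal U5M smoother",
                 "=" * 60,
                 f"counties: {self.model.K}   years: {self.posterior.years[0]}-"
                 f"{self.posterior.years[-1]}   observations: {len(self.model.obs)}",
                 f"retained posterior samples: {self.posterior.n_samples}",
                 "",
                 self.params_summary().round(4).to_string()]
        return "\n".join(lines)

    def county_series(self, county_id: str) -> pd.DataFrame:
        sf = self.summary_frame()
        return sf[sf["county_id"] == str(county_id)].reset_index(drop=True)

    def plot_county(self, county_id: str, ax=None, per_1000: bool = True):
        """Posterior mean and 95% band for one county over time."""
        import matplotlib.pyplot as plt
        series = self.county_series(county_id)
        if ax is None:
            _, ax = plt.subplots()
        scale = 1.0 if per_1000 else 1e-3
        ax.plot(series["year"], series["mean_per_1000"] * scale, color="k")
        ax.fill_between(series["year"], series["lo95"] * scale,
                        series["hi95"] * scale, alpha=0.3, color="green")
        ax.set_xlabel("year")
        ax.set_ylabel("U5M per 1000 live births" if per_1000 else "q5")
        ax.set_title(f"county {county_id}")
        return ax
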