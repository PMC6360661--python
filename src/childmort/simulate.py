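"""Synthetic birth-history generator.

Real under-five mortality (U5M) work of this kind rests on restricted
survey and census microdata.  This module generates data with the same
statistical structure so the whole estimation chain is testable end to end:

* a latent spatio-temporal mortality surface — a zero-mean Gaussian field
  with separable proper-CAR (space) x AR(1) (time) covariance, placed on
  the logit scale around an intercept ``alpha`` and mapped to per-county,
  per-year true U5M probabilities ``Q``;
* woman-level complete birth histories: interview ages uniform over 15-49,
  month-by-month fertility from age-specific rates, and child survival from
  a piecewise-constant monthly hazard over the six under-five age segments,
  calibrated so the implied q5 for a child's county and birth year equals
  the surface value;
* summary birth histories by aggregation (see :mod:`childmort.records`).

Fertility is independent of mortality (no replacement effects) and women do
not migrate between counties — both deliberate simplifications.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .gmrf import ar1_precision, car_precision
from .graphs import AdjacencyGraph
from .records import ChildRecord, WomanRecord

# Annual births per woman by 5-year maternal age group 15-19 ... 45-49;
# a high-fertility schedule typical of the East African setting emulated.
DEFAULT_FERTILITY = {
    "15-19": 0.10, "20-24": 0.25, "25-29": 0.24, "30-34": 0.20,
    "35-39": 0.14, "40-44": 0.06, "45-49": 0.02,
}

# Share of under-five deaths falling in each age segment
# [0, 1-11, 12-23, 24-35, 36-47, 48-59 months]; a declining pattern loosely
# mimicking model life tables.  Any non-negative split summing to 1 works.
DEFAULT_HAZARD_SPLIT = (0.35, 0.30, 0.15, 0.10, 0.06, 0.04)

SEGMENT_WIDTHS = (1, 11, 12, 12, 12, 12)  # months; sum to 60


@dataclass(frozen=True)
class SurveySpec:
    """One simulated data collection: a survey or census round."""

    year: int
    counties: tuple
    women_per_county: int
    collects_cbh: bool = True
    collects_sbh: bool = True

    def __post_init__(self):
        object.__setattr__(self, "counties", tuple(str(c) for c in self.counties))


@dataclass
class SimConfig:
    """Parameters of one synthetic study.

    The latent field is ``logit Q_kt = alpha + S_kt`` with S a separable
    CAR x AR(1) Gaussian field of marginal variance ``sigma2_S``.
    """

    K: int
    year_range: tuple  # inclusive (t_min, t_max)
    alpha: float = -2.0
    sigma2_S: float = 0.15
    rho_s: float = 0.9
    phi_t: float = 0.95
    tau2_by_method: dict = field(default_factory=lambda: {
        "direct": 0.01, "cohort_MA": 0.02, "cohort_TFB": 0.02,
        "period_MA": 0.02, "period_TFB": 0.02})
    hazard_split: tuple = DEFAULT_HAZARD_SPLIT
    fertility_rates: dict = field(default_factory=lambda: dict(DEFAULT_FERTILITY))
    surveys: tuple = ()
    seed: int = 0

    def __post_init__(self):
        self.year_range = (int(self.year_range[0]), int(self.year_range[1]))
        if self.year_range[1] < self.year_range[0]:
            raise ValueError("empty year range")
        if self.sigma2_S < 0:
            raise ValueError("sigma2_S must be >= 0")
        hs = np.asarray(self.hazard_split, dtype=float)
        if hs.shape != (6,) or (hs < 0).any() or abs(hs.sum() - 1.0) > 1e-9:
            raise ValueError("hazard_split must be 6 non-negative weights summing to 1")
        self.hazard_split = tuple(hs)
        self.surveys = tuple(self.surveys)
        for s in self.surveys:
            if s.year < self.year_range[0]:
                raise ValueError(f"survey year {s.year} precedes year range")

    @property
    def T(self) -> int:
        return self.year_range[1] - self.year_range[0] + 1

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.year_range[0], self.year_range[1] + 1)

    def fertility_monthly(self) -> np.ndarray:
        """Monthly birth probability indexed by age in months since 15y
        (length 35*12)."""
        out = np.empty(35 * 12)
        for i, g in enumerate(("15-19", "20-24", "25-29", "30-34",
                               "35-39", "40-44", "45-49")):
            out[i * 60:(i + 1) * 60] = self.fertility_rates[g] / 12.0
        return out


@dataclass
class TrueSurface:
    """Latent truth: S (logit-scale deviations) and Q = expit(alpha + S),
    both K x T in graph node order / calendar year order."""

    S: np.ndarray
    Q: np.ndarray
    county_ids: tuple
    years: np.ndarray

    def q5(self, county_id: str, year: int) -> float:
        k = self.county_ids.index(str(county_id))
        t = int(np.clip(year, self.years[0], self.years[-1])) - self.years[0]
        return float(self.Q[k, t])


def sample_true_surface(config: SimConfig, graph: AdjacencyGraph) -> TrueSurface:
    """Draw the latent mortality surface.

    S has separable covariance Sigma_space (x) Sigma_time — inverses of the
    proper-CAR and AR(1) precisions — rescaled so the average marginal
    variance equals ``sigma2_S``.  Sampling uses the matrix-normal form
    S = A Z B' with A, B Cholesky factors of the two covariance pieces.
    """
    if graph.n_nodes != config.K:
        raise ValueError(f"graph has {graph.n_nodes} nodes, config.K = {config.K}")
    K, T = config.K, config.T
    rng = np.random.default_rng([int(config.seed) % (2 ** 31), 101])
    if config.sigma2_S == 0.0:
        S = np.zeros((K, T))
    else:
        Sig_s = np.linalg.inv(car_precision(graph, config.rho_s))
        Sig_t = np.linalg.inv(ar1_precision(T, config.phi_t))
        # scale so mean_k,t Var(S_kt) = sigma2_S
        marg = np.outer(np.diag(Sig_s), np.diag(Sig_t)).mean()
        c = config.sigma2_S / marg
        A = np.linalg.cholesky(c * Sig_s)
        B = np.linalg.cholesky(Sig_t)
        S = A @ rng.standard_normal((K, T)) @ B.T
    Q = expit(config.alpha + S)
    return TrueSurface(S=S, Q=Q, county_ids=graph.node_ids, years=config.years)


def _segment_monthly_hazards(q5: np.ndarray, hazard_split) -> np.ndarray:
    """Monthly death probabilities (n, 6) such that the cumulative death
    probability over segment s is hazard_split[s] * q5 and the total is q5."""
    q5 = np.atleast_1d(np.asarray(q5, dtype=float))
    w = np.asarray(hazard_split)
    cum = np.concatenate([[0.0], np.cumsum(w)])
    # survival at segment boundaries: V_s = 1 - q5 * cum_s
    V = 1.0 - q5[:, None] * cum[None, :]
    if (V[:, -1] <= 0).any():
        raise ValueError("q5 = 1 with this hazard split is not representable")
    widths = np.asarray(SEGMENT_WIDTHS, dtype=float)
    m = 1.0 - (V[:, 1:] / V[:, :-1]) ** (1.0 / widths)
    return m


def _death_month_cdf(q5: np.ndarray, hazard_split) -> np.ndarray:
    """(n, 60) cumulative probability of death by end of each age month."""
    m = _segment_monthly_hazards(q5, hazard_split)
    log_surv_step = np.repeat(np.log1p(-m), SEGMENT_WIDTHS, axis=1)
    surv = np.exp(np.cumsum(log_surv_step, axis=1))
    return 1.0 - surv


def simulate_survey(config: SimConfig, surface: TrueSurface,
                    survey_index: int) -> list:
    """Simulate the woman records of one survey round.

    Women are interviewed mid-year of the survey year at ages uniform over
    15-49 (in months).  Births arise month by month from the age-specific
    fertility schedule; each child's survival follows the piecewise-constant
    hazard implied by the surface value for its county and birth year.
    Deaths that would occur after the interview month are censored and the
    child is recorded alive; a death in the interview month itself counts
    as observed.  Fully deterministic given ``config.seed``.
    """
    try:
        spec = config.surveys[survey_index]
    except IndexError:
        raise IndexError(f"survey_index {survey_index} out of range "
                         f"(config has {len(config.surveys)} surveys)") from None
    unknown = set(spec.counties) - set(surface.county_ids)
    if unknown:
        raise ValueError(f"survey covers counties not on the surface: {sorted(unknown)}")
    rng = np.random.default_rng([int(config.seed) % (2 ** 31), 7919, int(survey_index)])
    interview_month = spec.year * 12 + 6
    fert = config.fertility_monthly()
    n_fertile_max = fert.size  # 420 months of potential exposure
    records: list[WomanRecord] = []
    wid = survey_index * 10 ** 7
    for county in spec.counties:
        n = spec.women_per_county
        # age at interview in months, uniform over [15y, 50y)
        age_months = rng.integers(15 * 12, 50 * 12, size=n)
        exposure = np.minimum(age_months - 15 * 12, n_fertile_max)
        u = rng.random((n, n_fertile_max))
        births_mask = u < fert[None, :]
        births_mask &= np.arange(n_fertile_max)[None, :] < exposure[:, None]
        for i in range(n):
            w_birth = interview_month - int(age_months[i])
            offsets = np.flatnonzero(births_mask[i])
            children = []
            if offsets.size:
                child_bm = w_birth + 15 * 12 + offsets
                q5 = np.array([surface.q5(county, bm // 12) for bm in child_bm])
                cdf = _death_month_cdf(q5, config.hazard_split)
                uu = rng.random(offsets.size)
                dies = uu < cdf[:, -1]
                death_age = (uu[:, None] > cdf).sum(axis=1)
                for j in range(offsets.size):
                    dam = None
                    if dies[j]:
                        if child_bm[j] + int(death_age[j]) <= interview_month:
                            dam = int(death_age[j])
                    children.append(ChildRecord(int(child_bm[j]), dam))
            records.append(WomanRecord(wid, county, w_birth, interview_month,
                                       tuple(children)))
            wid += 1
    return records
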