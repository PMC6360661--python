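"""Indirect (Brass/Trussell-type) under-five mortality estimation from
summary birth histories.

Two families of methods, each indexed either by maternal age (MA) or by
time since first birth (TFB):

* **Cohort methods** convert each 5-year group's proportion of children
  dead, CD/CEB, to a q5 on the logit scale through a group-specific linear
  predictor that also uses mean parity and the parity ratios
  P(15-19)/P(20-24) and P(20-24)/P(25-29).  Each group's estimate refers to
  a fixed number of years before the interview (at most 18).
* **Period methods** first redistribute each group's reported CEB and CD
  over single years before the survey using empirical birth and death
  distributions, then convert each year's CD_t/CEB_t via a year-specific
  logit regression (horizon at most 25 years).

The regression coefficients in published applications come from external
pooled-survey fits that are not reproducible here; this module instead
ships :func:`calibrate_coefficients`, which estimates them by ordinary
least squares on a synthetic corpus whose ground truth is the direct
estimator applied to the same simulated populations.  Published coefficient
tables can be dropped in through the same CSV schema.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .direct import direct_estimates
from .records import MA_GROUPS, TFB_GROUPS, SBHTable, aggregate_sbh, records_to_frame

logger = logging.getLogger(__name__)

COHORT_HORIZON_YEARS = 18
PERIOD_HORIZON_YEARS = 25


class CalibrationError(RuntimeError):
    pass


@dataclass
class CohortCoefficients:
    """Per-group regression coefficients for the cohort conversion.

    ``table`` columns: group_label, beta0..beta4, u, ref_offset (years
    before interview the group's estimate refers to, increasing down the
    table, capped at 18).
    """

    grouping: str
    table: pd.DataFrame

    def __post_init__(self):
        r = self.table["ref_offset"].to_numpy()
        if (np.diff(r) < 0).any():
            raise ValueError("ref_offset must be non-decreasing across groups")
        if r.max() > COHORT_HORIZON_YEARS:
            raise ValueError(f"ref_offset exceeds {COHORT_HORIZON_YEARS}-year horizon")

    @classmethod
    def identity(cls, grouping: str = "MA", offsets=None) -> "CohortCoefficients":
        """beta1 = 1, everything else 0: q5 = CD/CEB exactly."""
        groups = MA_GROUPS if grouping == "MA" else TFB_GROUPS
        if offsets is None:
            offsets = np.linspace(1, COHORT_HORIZON_YEARS, len(groups))
        table = pd.DataFrame({
            "group_label": groups, "beta0": 0.0, "beta1": 1.0, "beta2": 0.0,
            "beta3": 0.0, "beta4": 0.0, "u": 0.0, "ref_offset": offsets})
        return cls(grouping, table)

    def to_csv(self, path):
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, grouping: str) -> "CohortCoefficients":
        return cls(grouping, pd.read_csv(path))


@dataclass
class PeriodCoefficients:
    """Per year-before-survey coefficients: columns years_before, beta0,
    beta1, u; horizon at most 25 years."""

    grouping: str
    table: pd.DataFrame

    def __post_init__(self):
        if self.table["years_before"].max() >= PERIOD_HORIZON_YEARS:
            raise ValueError(f"period horizon exceeds {PERIOD_HORIZON_YEARS} years")

    @classmethod
    def identity(cls, grouping: str = "MA",
                 horizon: int = PERIOD_HORIZON_YEARS) -> "PeriodCoefficients":
        table = pd.DataFrame({
            "years_before": np.arange(horizon), "beta0": 0.0, "beta1": 1.0,
            "u": 0.0})
        return cls(grouping, table)

    def to_csv(self, path):
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, grouping: str) -> "PeriodCoefficients":
        return cls(grouping, pd.read_csv(path))


@dataclass
class EmpiricalDistribution:
    """Per-group probability vectors over years-before-survey for births
    and deaths, used to redistribute SBH totals over calendar time."""

    grouping: str
    horizon: int
    births: dict = field(default_factory=dict)  # group -> array (horizon,)
    deaths: dict = field(default_factory=dict)

    def validate(self):
        for name, d in (("births", self.births), ("deaths", self.deaths)):
            for g, v in d.items():
                v = np.asarray(v, dtype=float)
                if v.shape != (self.horizon,) or (v < 0).any():
                    raise ValueError(f"{name} distribution for group {g} malformed")
                if abs(v.sum() - 1.0) > 1e-9:
                    raise ValueError(
                        f"{name} distribution for group {g} sums to {v.sum():.12f}, not 1")
        return self

    @classmethod
    def uniform(cls, grouping: str = "MA", horizon: int = 5) -> "EmpiricalDistribution":
        groups = MA_GROUPS if grouping == "MA" else TFB_GROUPS
        v = np.full(horizon, 1.0 / horizon)
        return cls(grouping, horizon,
                   {g: v.copy() for g in groups}, {g: v.copy() for g in groups})

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g in self.births:
            for t in range(self.horizon):
                rows.append((g, t, self.births[g][t], self.deaths[g][t]))
        return pd.DataFrame(rows, columns=["group_label", "years_before",
                                           "birth_prob", "death_prob"])

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, grouping: str) -> "EmpiricalDistribution":
        horizon = int(frame["years_before"].max()) + 1
        births, deaths = {}, {}
        for g, sub in frame.groupby("group_label"):
            sub = sub.sort_values("years_before")
            births[g] = sub["birth_prob"].to_numpy()
            deaths[g] = sub["death_prob"].to_numpy()
        return cls(grouping, horizon, births, deaths).validate()


def parity_ratios(sbh: SBHTable) -> tuple:
    """(P(15-19)/P(20-24), P(20-24)/P(25-29)) from a maternal-age table."""
    if sbh.grouping != "MA":
        raise ValueError("parity ratios are defined on the maternal-age grouping")
    parities = {}
    for g in ("15-19", "20-24", "25-29"):
        row = sbh.row(g)
        if row["women"] <= 0:
            raise ValueError(f"no women in group {g}; parity undefined")
        parities[g] = row["ceb"] / row["women"]
    if parities["20-24"] == 0 or parities["25-29"] == 0:
        raise ZeroDivisionError("zero parity in denominator group")
    return (parities["15-19"] / parities["20-24"],
            parities["20-24"] / parities["25-29"])


def cohort_q5(sbh: SBHTable, coeffs: CohortCoefficients, ratios: tuple) -> list:
    """Per-group (q5, reference_year) via the cohort logit conversion.

    Groups with CD = 0, CD = CEB, or no women are skipped with a log entry
    (the logit of the dead proportion is undefined there).
    """
    if sbh.grouping != coeffs.grouping:
        raise ValueError("SBH grouping does not match coefficient grouping")
    r1, r2 = ratios
    out = []
    for _, c in coeffs.table.iterrows():
        g = c["group_label"]
        try:
            row = sbh.row(g)
        except KeyError:
            raise CalibrationError(f"missing coefficient/SBH row for group {g}")
        W, ceb, cd = row["women"], row["ceb"], row["cd"]
        if W <= 0 or ceb <= 0 or cd <= 0 or cd >= ceb:
            logger.info("cohort_q5: skipping group %s (W=%s CEB=%s CD=%s)",
                        g, W, ceb, cd)
            continue
        mean_ceb = ceb / W
        eta = (c["beta0"] + c["u"] + c["beta1"] * logit(cd / ceb)
               + c["beta2"] * mean_ceb + c["beta3"] * r1 + c["beta4"] * r2)
        ref_year = sbh.interview_year - float(c["ref_offset"])
        out.append((float(expit(eta)), ref_year, g))
    return out


def period_redistribute(sbh: SBHTable, dist: EmpiricalDistribution) -> pd.DataFrame:
    """Spread each group's CEB and CD over years before the survey.

    CEB_t = sum_g CEB_g * birth_dist_g(t) and likewise for CD with the
    death distributions; the year sums conserve the group totals exactly
    (up to float round-off) because each distribution sums to 1.
    """
    if sbh.grouping != dist.grouping:
        raise ValueError("SBH grouping does not match distribution grouping")
    dist.validate()
    ceb_t = np.zeros(dist.horizon)
    cd_t = np.zeros(dist.horizon)
    for _, row in sbh.table.iterrows():
        g = row["group_label"]
        if g not in dist.births:
            raise ValueError(f"no empirical distribution for group {g}")
        ceb_t += row["ceb"] * dist.births[g]
        cd_t += row["cd"] * dist.deaths[g]
    return pd.DataFrame({"years_before": np.arange(dist.horizon),
                         "ceb": ceb_t, "cd": cd_t})


def period_q5(per_year: pd.DataFrame, coeffs: PeriodCoefficients,
              interview_year: int) -> list:
    """Per-year (q5, calendar year) via the period logit conversion;
    years with CD_t = 0 or CEB_t = 0 (or beyond the coefficient horizon)
    are skipped."""
    ctab = coeffs.table.set_index("years_before")
    out = []
    for _, row in per_year.iterrows():
        t = int(row["years_before"])
        if t not in ctab.index:
            continue
        ceb, cd = row["ceb"], row["cd"]
        if ceb <= 0 or cd <= 0 or cd >= ceb:
            logger.info("period_q5: skipping year t=%d (CEB=%.2f CD=%.2f)", t, ceb, cd)
            continue
        c = ctab.loc[t]
        eta = c["beta0"] + c["u"] + c["beta1"] * logit(cd / ceb)
        out.append((float(expit(eta)), interview_year - t))
    return out


# ---------------------------------------------------------------------------
# calibration on a synthetic corpus
# ---------------------------------------------------------------------------

def _child_month_reference(records, grouping: str):
    """Exposure-weighted mean years-before-interview of each group's
    under-five child-months, plus birth/death year-before tallies."""
    groups = MA_GROUPS if grouping == "MA" else TFB_GROUPS
    exp_sum = {g: 0.0 for g in groups}
    exp_wt = {g: 0.0 for g in groups}
    births = {g: np.zeros(PERIOD_HORIZON_YEARS) for g in groups}
    deaths = {g: np.zeros(PERIOD_HORIZON_YEARS) for g in groups}
    for w in records:
        if grouping == "MA":
            lo = (w.age_years - 15) // 5
            g = groups[lo] if 0 <= lo < len(groups) else None
        else:
            if not w.children:
                continue
            first = min(ch.birth_month for ch in w.children)
            lo = ((w.interview_month - first) // 12) // 5
            g = groups[lo] if 0 <= lo < len(groups) else None
        if g is None:
            continue
        for ch in w.children:
            months_lived = (ch.death_age_months if ch.death_age_months is not None
                            else min(59, w.interview_month - ch.birth_month))
            # mean months-before-interview of ages 0..months_lived
            mean_before = w.interview_month - ch.birth_month - months_lived / 2.0
            n_months = months_lived + 1
            exp_sum[g] += n_months * mean_before / 12.0
            exp_wt[g] += n_months
            yb = (w.interview_month - ch.birth_month) // 12
            if yb < PERIOD_HORIZON_YEARS:
                births[g][yb] += 1
            if ch.death_age_months is not None:
                dyb = (w.interview_month - ch.birth_month - ch.death_age_months) // 12
                if 0 <= dyb < PERIOD_HORIZON_YEARS:
                    deaths[g][dyb] += 1
    refs = {g: (exp_sum[g] / exp_wt[g] if exp_wt[g] > 0 else np.nan)
            for g in groups}
    return refs, births, deaths


def _nearest_direct(series: pd.DataFrame, year: float, max_gap: float = 1.5):
    if series.empty:
        return None
    gaps = (series["year"] - year).abs()
    i = gaps.idxmin()
    if gaps.loc[i] > max_gap:
        return None
    return series.loc[i, "q5"]


def _check_variation(X: np.ndarray, names):
    for j, name in enumerate(names):
        if np.std(X[:, j]) < 1e-12:
            raise CalibrationError(f"no variation in regressor {name!r}")


def calibrate_coefficients(corpus, grouping: str = "MA"):
    """Fit cohort and period coefficients on a synthetic survey corpus.

    ``corpus`` is a list of surveys, each a list of WomanRecords with
    complete birth histories.  For every survey the direct estimator on the
    same population provides the ground-truth q5 series; coefficients are
    then ordinary least squares of logit(true q5) on the cohort/period
    regressors.  The country offset U is identically 0 (a single synthetic
    "region" absorbs it into the intercept); reference offsets are the
    exposure-weighted mean years-before-interview of each group's
    under-five child-months, pooled over the corpus.

    Returns (CohortCoefficients, PeriodCoefficients, EmpiricalDistribution).
    """
    if len(corpus) < 20:
        raise CalibrationError(
            f"corpus must span at least 20 surveys, got {len(corpus)}")
    groups = MA_GROUPS if grouping == "MA" else TFB_GROUPS

    # pooled reference offsets and empirical distributions
    pooled_births = {g: np.zeros(PERIOD_HORIZON_YEARS) for g in groups}
    pooled_deaths = {g: np.zeros(PERIOD_HORIZON_YEARS) for g in groups}
    ref_acc = {g: [] for g in groups}
    per_survey = []
    for records in corpus:
        refs, births, deaths = _child_month_reference(records, grouping)
        for g in groups:
            pooled_births[g] += births[g]
            pooled_deaths[g] += deaths[g]
            if np.isfinite(refs[g]):
                ref_acc[g].append((refs[g], births[g].sum()))
        frame = records_to_frame(records)
        direct = direct_estimates(frame, by_county=False)
        sbh = aggregate_sbh(records, grouping=grouping)
        sbh_ma = sbh if grouping == "MA" else aggregate_sbh(records, grouping="MA")
        ratios = parity_ratios(sbh_ma)
        per_survey.append((records, sbh, ratios, direct))

    ref_offsets = {}
    for g in groups:
        if ref_acc[g]:
            vals, wts = zip(*ref_acc[g])
            ref_offsets[g] = min(float(np.average(vals, weights=wts)),
                                 COHORT_HORIZON_YEARS)
        else:
            ref_offsets[g] = np.nan
    # enforce monotone non-decreasing offsets across groups
    last = 0.0
    for g in groups:
        if np.isnan(ref_offsets[g]):
            ref_offsets[g] = last
        ref_offsets[g] = max(ref_offsets[g], last)
        last = ref_offsets[g]

    dist = EmpiricalDistribution(grouping, PERIOD_HORIZON_YEARS)
    for g in groups:
        b, d = pooled_births[g], pooled_deaths[g]
        dist.births[g] = b / b.sum() if b.sum() > 0 else np.full(
            PERIOD_HORIZON_YEARS, 1.0 / PERIOD_HORIZON_YEARS)
        dist.deaths[g] = d / d.sum() if d.sum() > 0 else dist.births[g].copy()
    dist.validate()

    # cohort OLS per group
    cohort_rows = []
    for g in groups:
        ys, Xs = [], []
        for records, sbh, ratios, direct in per_survey:
            row = sbh.row(g)
            W, ceb, cd = row["women"], row["ceb"], row["cd"]
            if W <= 0 or ceb <= 0 or cd <= 0 or cd >= ceb:
                continue
            truth = _nearest_direct(direct, sbh.interview_year - ref_offsets[g])
            if truth is None or not 0 < truth < 1:
                continue
            ys.append(logit(truth))
            Xs.append([1.0, logit(cd / ceb), ceb / W, ratios[0], ratios[1]])
        if len(ys) < 6:
            logger.warning("calibrate: group %s has only %d usable surveys; "
                           "falling back to identity conversion", g, len(ys))
            cohort_rows.append((g, 0.0, 1.0, 0.0, 0.0, 0.0))
            continue
        X = np.asarray(Xs)
        _check_variation(X[:, 1:], ["logit(CD/CEB)", "mean CEB",
                                    "parity ratio 1", "parity ratio 2"])
        beta, *_ = np.linalg.lstsq(X, np.asarray(ys), rcond=None)
        cohort_rows.append((g, *beta))
    cohort = CohortCoefficients(grouping, pd.DataFrame(
        [(g, b0, b1, b2, b3, b4, 0.0, ref_offsets[g])
         for g, b0, b1, b2, b3, b4 in cohort_rows],
        columns=["group_label", "beta0", "beta1", "beta2", "beta3", "beta4",
                 "u", "ref_offset"]))

    # period OLS per year-before-survey
    period_rows = []
    for t in range(PERIOD_HORIZON_YEARS):
        ys, xs = [], []
        for records, sbh, ratios, direct in per_survey:
            per_year = period_redistribute(sbh, dist)
            row = per_year[per_year["years_before"] == t].iloc[0]
            if row["ceb"] <= 0 or row["cd"] <= 0 or row["cd"] >= row["ceb"]:
                continue
            truth = _nearest_direct(direct, sbh.interview_year - t)
            if truth is None or not 0 < truth < 1:
                continue
            ys.append(logit(truth))
            xs.append(logit(row["cd"] / row["ceb"]))
        if len(ys) < 6 or np.std(xs) < 1e-12:
            period_rows.append((t, 0.0, 1.0, 0.0))
            continue
        b1, b0 = np.polyfit(xs, ys, 1)
        period_rows.append((t, b0, b1, 0.0))
    period = PeriodCoefficients(grouping, pd.DataFrame(
        period_rows, columns=["years_before", "beta0", "beta1", "u"]))
    return cohort, period, dist


def indirect_estimates(sbh: SBHTable, cohort: CohortCoefficients,
                       period: PeriodCoefficients, dist: EmpiricalDistribution,
                       ratios: tuple) -> pd.DataFrame:
    """All cohort- and period-method estimates from one SBH table.

    Returns columns county_id, year, q5, n_women, method with method in
    {cohort_<grouping>, period_<grouping>}.
    """
    n_women = int(sbh.table["women"].sum())
    rows = []
    for q5, ref_year, g in cohort_q5(sbh, cohort, ratios):
        w = int(sbh.row(g)["women"])
        rows.append((sbh.county_id, int(round(ref_year)), q5, w,
                     f"cohort_{sbh.grouping}"))
    per_year = period_redistribute(sbh, dist)
    for q5, year, in period_q5(per_year, period, sbh.interview_year):
        rows.append((sbh.county_id, int(year), q5, n_women,
                     f"period_{sbh.grouping}"))
    return pd.DataFrame(rows, columns=["county_id", "year", "q5",
                                       "n_women", "method"])
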