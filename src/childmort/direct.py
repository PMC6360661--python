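"""Direct (synthetic-cohort) under-five mortality estimation from complete
birth histories.

Each child's months lived before death or exact age five are allocated to
six age segments — [0], [1-11], [12-23], [24-35], [36-47], [48-59] months —
and to consecutive periods (default two years) counted backwards from the
interview.  Within a segment and period the monthly death risk is
m = D / E (deaths over child-months of exposure), the monthly survival
probability is P = 1 - m, and

    q5 = 1 - P_1^1 * P_2^11 * P_3^12 * P_4^12 * P_5^12 * P_6^12,

the exponents being the segment widths in months.  The death month counts
as a full month of exposure; exposure is censored at the interview month.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

SEGMENT_WIDTHS = np.array([1, 11, 12, 12, 12, 12])
SEGMENT_STARTS = np.array([0, 1, 12, 24, 36, 48])


def segment_of_age(age_months) -> np.ndarray:
    """Age segment index 0..5 for ages 0..59 months."""
    return np.searchsorted(SEGMENT_STARTS, np.asarray(age_months), side="right") - 1


@dataclass
class ExposureTable:
    """Deaths D and exposure E (child-months) per (period, segment).

    Period p covers months-before-interview [p*period_months,
    (p+1)*period_months); p = 0 is the most recent period.  ``midpoint_month``
    maps each period to the calendar month at its centre (per-child interview
    months are averaged when they differ).
    """

    counts: pd.DataFrame  # index (period, segment), columns D, E
    period_months: int
    midpoint_month: dict  # period -> calendar month index
    n_women: int
    n_children: int

    def periods(self):
        return sorted({p for p, _ in self.counts.index})


@dataclass
class DirectEstimate:
    county_id: str | None
    year: int
    q5: float
    n_women: int
    n_children: int
    defined: bool = True


def tabulate_exposure(children: pd.DataFrame, period_months: int = 24) -> ExposureTable:
    """Tabulate deaths and exposure from a CBH child frame.

    ``children`` needs columns child_birth_month, interview_month,
    death_age_months (NaN when alive) and woman_id; rows with NaN
    child_birth_month (childless women) contribute women counts only.
    """
    if period_months < 1:
        raise ValueError("period_months must be >= 1")
    if children.empty:
        raise ValueError("no records to tabulate")
    n_women = children["woman_id"].nunique()
    kids = children.dropna(subset=["child_birth_month"])
    bad = kids["death_age_months"] > 59
    if bad.any():
        raise ValueError(
            f"{int(bad.sum())} record(s) with death_age_months > 59 "
            "(outside the under-five range); first offending rows: "
            f"{kids.index[bad][:5].tolist()}")
    birth = kids["child_birth_month"].to_numpy(dtype=int)
    interview = kids["interview_month"].to_numpy(dtype=int)
    dam = kids["death_age_months"].to_numpy(dtype=float)  # NaN = alive
    died = ~np.isnan(dam)
    # last month of age lived (inclusive): death month, or censoring at
    # interview / exact age five
    last = np.where(died, dam, 59).astype(int)
    last = np.minimum(last, interview - birth)

    counts: dict[tuple[int, int], list] = {}
    for a in range(60):
        live = last >= a
        if not live.any():
            continue
        cal = birth[live] + a
        before = interview[live] - cal  # months before interview, >= 0
        period = before // period_months
        seg = int(segment_of_age(a))
        for p in np.unique(period):
            key = (int(p), seg)
            e = int((period == p).sum())
            counts.setdefault(key, [0, 0])[1] += e
    # deaths: segment of death age, period of death calendar month
    if died.any():
        d_age = dam[died].astype(int)
        observable = d_age <= (interview[died] - birth[died])
        d_age = d_age[observable]
        d_cal = birth[died][observable] + d_age
        d_before = interview[died][observable] - d_cal
        d_period = d_before // period_months
        d_seg = segment_of_age(d_age)
        for p, s in zip(d_period, d_seg):
            counts.setdefault((int(p), int(s)), [0, 0])[0] += 1
    # period midpoints: average interview month minus period centre
    mean_interview = float(interview.mean()) if len(interview) else float(
        children["interview_month"].mean())
    midpoints = {}
    for p, _ in counts:
        midpoints[p] = int(round(mean_interview - (p + 0.5) * period_months))
    idx = pd.MultiIndex.from_tuples(sorted(counts), names=["period", "segment"])
    frame = pd.DataFrame(
        [counts[k] for k in sorted(counts)], index=idx, columns=["D", "E"])
    return ExposureTable(counts=frame, period_months=period_months,
                         midpoint_month=midpoints, n_women=int(n_women),
                         n_children=int(len(kids)))


def q5_direct(table: ExposureTable, county_id: str | None = None) -> list:
    """Synthetic-cohort q5 per period from an exposure table.

    Periods in which any age segment has zero exposure yield an estimate
    flagged undefined (q5 = NaN) rather than a silent zero.
    """
    out = []
    for p in table.periods():
        D = np.zeros(6)
        E = np.zeros(6)
        sub = table.counts.loc[p]
        D[sub.index] = sub["D"].to_numpy()
        E[sub.index] = sub["E"].to_numpy()
        year = table.midpoint_month[p] // 12
        if (E <= 0).any():
            out.append(DirectEstimate(county_id, year, float("nan"),
                                      table.n_women, table.n_children,
                                      defined=False))
            continue
        m = D / E
        q5 = 1.0 - float(np.prod((1.0 - m) ** SEGMENT_WIDTHS))
        out.append(DirectEstimate(county_id, year, q5,
                                  table.n_women, table.n_children))
    return out


def direct_estimates(children: pd.DataFrame, period_months: int = 24,
                     by_county: bool = True) -> pd.DataFrame:
    """Direct q5 series, per county or pooled (national).

    Returns a frame with columns county_id, year, q5, n_women, n_children,
    method; undefined periods are dropped.
    """
    groups = (children.groupby("county_id") if by_county
              else [(None, children)])
    rows = []
    for county, sub in groups:
        table = tabulate_exposure(sub, period_months=period_months)
        for est in q5_direct(table, county_id=county):
            if est.defined:
                rows.append((est.county_id, est.year, est.q5,
                             est.n_women, est.n_children))
    return pd.DataFrame(rows, columns=["county_id", "year", "q5",
                                       "n_women", "n_children"]).assign(method="direct")
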