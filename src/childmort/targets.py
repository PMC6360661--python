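"""Mortality-reduction targets, projections and between-county inequality.

Works on posterior-mean U5M series per county (deaths per 1000 live
births).  The annual rate of reduction (ARR) assumes exponential change
between two time points; projections compound it forward.  Goal rules:

* World Summit for Children (by 2000): U5M <= 70 per 1000 and/or at least
  a one-third reduction between 1990 and 2000 (either branch suffices).
* MDG 4 (by 2015): at least a two-thirds reduction between 1990 and 2015,
  the 2015 value projected from the 2000-2013 ARR.
* SDG 3.2 (by 2030): U5M <= 25 per 1000, evaluated only when a 2030 value
  is supplied — long-range projections to 2030 are deliberately not made.

A target missed by no more than a 20% relative margin is classed
"near_miss" (the "amber" band of the source tables).  Inequality between
counties is a Palma-adapted ratio: mean U5M of the worst-off 40% of
counties over mean U5M of the best-off 10%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

WSC_LEVEL = 70.0          # per 1000, by 2000
WSC_REDUCTION = 1.0 / 3.0  # 1990-2000
MDG4_REDUCTION = 2.0 / 3.0  # 1990-2015
SDG_LEVEL = 25.0          # per 1000, by 2030
NEAR_MISS_MARGIN = 0.20


def arr(u5m_start: float, u5m_end: float, n_years: int,
        continuous: bool = False) -> float:
    """Annual rate of reduction between two U5M levels.

    Discrete compounding by default: ARR = 1 - (end/start)^(1/n);
    ``continuous=True`` gives the log form log(start/end)/n instead.
    Negative when mortality rises.
    """
    if u5m_start <= 0 or u5m_end <= 0:
        raise ValueError("U5M rates must be positive")
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    if continuous:
        return float(np.log(u5m_start / u5m_end) / n_years)
    return float(1.0 - (u5m_end / u5m_start) ** (1.0 / n_years))


def project(u5m: float, arr_value: float, n_years: int) -> float:
    """Forward projection at a constant ARR: u5m * (1 - ARR)^n.

    Satisfies the round-trip identity project(a, arr(a, b, n), n) = b.
    """
    if u5m <= 0:
        raise ValueError("U5M rate must be positive")
    if arr_value >= 1:
        raise ValueError("arr_value must be < 1")
    return float(u5m * (1.0 - arr_value) ** n_years)


@dataclass
class CountySeries:
    """Per-year posterior-mean U5M for one county, per 1000 live births."""

    county_id: str
    values: pd.Series  # index: calendar year

    def __post_init__(self):
        if (self.values <= 0).any():
            raise ValueError("U5M series must be positive")

    def at(self, year: int) -> float:
        if year not in self.values.index:
            raise KeyError(f"county {self.county_id}: no value for year {year}")
        return float(self.values.loc[year])


def _classify_level(value: float, threshold: float) -> str:
    if value <= threshold:
        return "achieved"
    if value <= threshold * (1.0 + NEAR_MISS_MARGIN):
        return "near_miss"
    return "missed"


def _classify_reduction(reduction: float, required: float) -> str:
    if reduction >= required:
        return "achieved"
    if reduction >= required * (1.0 - NEAR_MISS_MARGIN):
        return "near_miss"
    return "missed"


_RANK = {"achieved": 0, "near_miss": 1, "missed": 2}


@dataclass
class TargetAssessment:
    county_id: str
    u5m_1990: float
    u5m_2000: float
    u5m_2013: float
    u5m_2015_projected: float
    arr_2000_2013: float
    wsc_achieved: bool
    mdg4_achieved: bool
    wsc_class: str
    mdg4_class: str
    sdg_achieved: bool | None = None

    @property
    def margin_class(self) -> str:
        """Margin class on the binding (most recent) target, MDG 4."""
        return self.mdg4_class


def assess_targets(series: CountySeries,
                   arr_window: tuple = (2000, 2013)) -> TargetAssessment:
    """Classify one county against the WSC, MDG 4 and (optionally) SDG
    goals.  The series must cover 1990 through the end of the ARR window;
    the 2015 value is projected from the window's ARR.
    """
    y0, y1 = arr_window
    for year in (1990, 2000, y0, y1):
        if year not in series.values.index:
            raise KeyError(f"county {series.county_id}: series lacks year {year}")
    v1990, v2000 = series.at(1990), series.at(2000)
    v_end = series.at(y1)
    arr_win = arr(series.at(y0), v_end, y1 - y0)
    v2015 = project(v_end, arr_win, 2015 - y1)

    wsc_level = _classify_level(v2000, WSC_LEVEL)
    wsc_red = _classify_reduction(1.0 - v2000 / v1990, WSC_REDUCTION)
    wsc_class = min(wsc_level, wsc_red, key=_RANK.get)  # either branch suffices
    mdg4_class = _classify_reduction(1.0 - v2015 / v1990, MDG4_REDUCTION)

    sdg = None
    if 2030 in series.values.index:
        sdg = series.at(2030) <= SDG_LEVEL
    return TargetAssessment(
        county_id=series.county_id,
        u5m_1990=v1990, u5m_2000=v2000, u5m_2013=v_end,
        u5m_2015_projected=v2015, arr_2000_2013=arr_win,
        wsc_achieved=wsc_class == "achieved",
        mdg4_achieved=mdg4_class == "achieved",
        wsc_class=wsc_class, mdg4_class=mdg4_class, sdg_achieved=sdg)


def assess_all(summary: pd.DataFrame,
               arr_window: tuple = (2000, 2013)) -> pd.DataFrame:
    """Assessment table from a posterior summary frame
    (columns county_id, year, mean_per_1000)."""
    rows = []
    for county, sub in summary.groupby("county_id"):
        series = CountySeries(str(county),
                              sub.set_index("year")["mean_per_1000"])
        a = assess_targets(series, arr_window)
        rows.append((a.county_id, a.u5m_1990, a.u5m_2000, a.u5m_2013,
                     a.u5m_2015_projected, a.arr_2000_2013,
                     a.wsc_class, a.mdg4_class))
    return pd.DataFrame(rows, columns=[
        "county_id", "u5m_1990", "u5m_2000", "u5m_2013",
        "u5m_2015_projected", "arr_2000_2013", "wsc", "mdg4"])


def inequality_ratio(values) -> float:
    """Palma-adapted between-county inequality for one year.

    mean U5M of the round(0.4 K) highest-mortality counties divided by the
    mean of the round(0.1 K) lowest; scale-invariant and always >= 1.
    """
    v = np.sort(np.asarray(values, dtype=float))[::-1]
    K = v.size
    if K < 10:
        raise ValueError(f"need at least 10 counties, got {K}")
    if (v <= 0).any():
        raise ValueError("U5M rates must be positive")
    n_high = int(np.floor(0.4 * K + 0.5))
    n_low = int(np.floor(0.1 * K + 0.5))
    return float(v[:n_high].mean() / v[-n_low:].mean())


def inequality_series(summary: pd.DataFrame) -> pd.DataFrame:
    """Inequality ratio per year from a posterior summary frame."""
    rows = []
    for year, sub in summary.groupby("year"):
        rows.append((int(year), inequality_ratio(sub["mean_per_1000"])))
    return pd.DataFrame(rows, columns=["year", "inequality_ratio"])
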