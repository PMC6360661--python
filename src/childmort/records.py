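"""Birth-history microdata containers and summary aggregation.

Complete birth histories (CBH) are per-child records: each woman aged 15-49
at interview reports the birth month of every live birth and, for children
who died before the interview, the age at death in months.  Summary birth
histories (SBH) aggregate, per group of women, children ever born (CEB) and
children dead (CD).

Time is discretized to calendar months: a "month index" is
``year * 12 + month_within_year``, so ``index // 12`` recovers the calendar
year.  Month arithmetic is the finest grain any estimator here needs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MA_GROUPS = ("15-19", "20-24", "25-29", "30-34", "35-39", "40-44", "45-49")
TFB_GROUPS = ("0-4", "5-9", "10-14", "15-19", "20-24")


@dataclass(frozen=True)
class ChildRecord:
    """One live birth; ``death_age_months`` is None for children alive
    (or censored) at interview, else an integer age at death in [0, 59]."""

    birth_month: int
    death_age_months: int | None = None


@dataclass(frozen=True)
class WomanRecord:
    woman_id: int
    county_id: str
    birth_month: int
    interview_month: int
    children: tuple = field(default_factory=tuple)

    def __post_init__(self):
        age_years = (self.interview_month - self.birth_month) // 12
        if not 15 <= age_years <= 49:
            raise ValueError(f"woman {self.woman_id}: interview age {age_years} outside 15-49")
        for ch in self.children:
            if ch.birth_month > self.interview_month:
                raise ValueError(f"woman {self.woman_id}: child born after interview")
            if ch.death_age_months is not None:
                if ch.birth_month + ch.death_age_months > self.interview_month:
                    raise ValueError(f"woman {self.woman_id}: death after interview month")

    @property
    def age_years(self) -> int:
        return (self.interview_month - self.birth_month) // 12


@dataclass
class SBHTable:
    """Summary-birth-history aggregates by 5-year group.

    ``grouping`` is "MA" (maternal age at interview) or "TFB" (time since
    first birth).  ``table`` has one row per group with columns
    ``group_label, women, ceb, cd``.
    """

    grouping: str
    table: pd.DataFrame
    interview_year: int
    county_id: str | None = None

    def __post_init__(self):
        if self.grouping not in ("MA", "TFB"):
            raise ValueError(f"unknown grouping {self.grouping!r}")
        t = self.table
        if (t["cd"] > t["ceb"]).any():
            raise ValueError("children dead exceeds children ever born in a group")
        if (t[["women", "ceb", "cd"]] < 0).to_numpy().any():
            raise ValueError("negative count in SBH table")

    def row(self, group_label: str) -> pd.Series:
        hit = self.table[self.table["group_label"] == group_label]
        if hit.empty:
            raise KeyError(group_label)
        return hit.iloc[0]


def _group_label(value: int, groups: tuple) -> str | None:
    for g in groups:
        lo, hi = (int(x) for x in g.split("-"))
        if lo <= value <= hi:
            return g
    return None


def aggregate_sbh(records, grouping: str = "MA",
                  county_id: str | None = None) -> SBHTable:
    """Aggregate woman records into an SBH table.

    Under the TFB grouping, childless women (no first birth to date from)
    and women whose first birth lies beyond the 20-24 group are excluded
    and logged.  Group sums of CEB and CD conserve the microdata totals
    over the included women exactly.
    """
    records = list(records)
    if not records:
        raise ValueError("no woman records to aggregate")
    groups = MA_GROUPS if grouping == "MA" else TFB_GROUPS
    counts = {g: [0, 0, 0] for g in groups}  # women, ceb, cd
    excluded = 0
    for w in records:
        if grouping == "MA":
            key = _group_label(w.age_years, groups)
        else:
            if not w.children:
                excluded += 1
                continue
            first = min(ch.birth_month for ch in w.children)
            tsfb = (w.interview_month - first) // 12
            key = _group_label(tsfb, groups)
            if key is None:
                excluded += 1
                continue
        if key is None:  # MA grouping covers 15-49 by construction
            raise ValueError(f"woman {w.woman_id} age {w.age_years} outside groups")
        c = counts[key]
        c[0] += 1
        c[1] += len(w.children)
        c[2] += sum(1 for ch in w.children if ch.death_age_months is not None)
    if excluded:
        logger.info("aggregate_sbh(%s): excluded %d women outside grouping", grouping, excluded)
    table = pd.DataFrame(
        [(g, *counts[g]) for g in groups],
        columns=["group_label", "women", "ceb", "cd"],
    )
    year = int(np.median([w.interview_month // 12 for w in records]))
    return SBHTable(grouping=grouping, table=table, interview_year=year, county_id=county_id)


def records_to_frame(records) -> pd.DataFrame:
    """Flatten woman records to one row per child (childless women keep one
    row with blank child columns), matching the CBH CSV schema."""
    rows = []
    for w in records:
        if not w.children:
            rows.append((w.woman_id, w.county_id, w.birth_month, w.interview_month,
                         np.nan, np.nan))
        for ch in w.children:
            rows.append((w.woman_id, w.county_id, w.birth_month, w.interview_month,
                         ch.birth_month,
                         np.nan if ch.death_age_months is None else ch.death_age_months))
    return pd.DataFrame(rows, columns=[
        "woman_id", "county_id", "woman_birth_month", "interview_month",
        "child_birth_month", "death_age_months"])


def frame_to_records(frame: pd.DataFrame) -> list:
    """Inverse of :func:`records_to_frame`."""
    records = []
    for (wid, county, wbm, im), grp in frame.groupby(
            ["woman_id", "county_id", "woman_birth_month", "interview_month"], sort=True):
        children = []
        for _, r in grp.iterrows():
            if pd.isna(r["child_birth_month"]):
                continue
            dam = r["death_age_months"]
            children.append(ChildRecord(
                birth_month=int(r["child_birth_month"]),
                death_age_months=None if pd.isna(dam) else int(dam)))
        records.append(WomanRecord(int(wid), str(county), int(wbm), int(im),
                                   tuple(children)))
    return records
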