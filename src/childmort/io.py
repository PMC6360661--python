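"""File schemas and validation.

All tabular interchange is CSV (UTF-8, header row); adjacency graphs are
whitespace edge lists; configuration is YAML.  Schemas:

* CBH: woman_id, county_id, woman_birth_month, interview_month,
  child_birth_month, death_age_months (blank when alive)
* SBH: county_id, grouping, group_label, women, ceb, cd
* estimates: survey_id, method, county_id, year, q5, n
* posterior summary: county_id, year, mean_per_1000, lo95, hi95
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

CBH_COLUMNS = ["woman_id", "county_id", "woman_birth_month", "interview_month",
               "child_birth_month", "death_age_months"]
SBH_COLUMNS = ["county_id", "grouping", "group_label", "women", "ceb", "cd"]
ESTIMATE_COLUMNS = ["survey_id", "method", "county_id", "year", "q5", "n"]


def read_csv(path, schema: str) -> pd.DataFrame:
    columns = {"cbh": CBH_COLUMNS, "sbh": SBH_COLUMNS,
               "estimates": ESTIMATE_COLUMNS}[schema]
    try:
        frame = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed CSV {path}: {exc}") from exc
    missing = set(columns) - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return frame


@dataclass
class Violation:
    file: str
    row: int  # 1-based data row number
    message: str

    def __str__(self):
        return f"{self.file}:row {self.row}: {self.message}"


@dataclass
class ValidationReport:
    violations: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def add(self, file, row, message):
        self.violations.append(Violation(str(file), int(row), message))

    def __len__(self):
        return len(self.violations)

    def __str__(self):
        if self.ok:
            return "all inputs valid"
        return "\n".join(str(v) for v in self.violations)


def _rows(mask) -> list:
    return (np.flatnonzero(np.asarray(mask)) + 1).tolist()


def validate_inputs(paths: dict, year_range: tuple | None = None) -> ValidationReport:
    """Schema and range checks over input files.

    ``paths`` maps schema name ("cbh" | "sbh" | "estimates") to a file
    path.  Every violation is reported with its 1-based data row number.
    """
    report = ValidationReport()
    for schema, path in paths.items():
        try:
            frame = read_csv(path, schema)
        except ValueError as exc:
            report.add(path, 0, str(exc))
            continue
        if schema == "cbh":
            kids = frame["child_birth_month"].notna()
            dam = frame["death_age_months"]
            for r in _rows(kids & dam.notna() & ((dam < 0) | (dam > 59))):
                report.add(path, r, "death_age_months outside [0, 59]")
            for r in _rows(kids & (frame["child_birth_month"] > frame["interview_month"])):
                report.add(path, r, "child born after interview")
            age = (frame["interview_month"] - frame["woman_birth_month"]) // 12
            for r in _rows((age < 15) | (age > 49)):
                report.add(path, r, f"woman's interview age outside 15-49")
        elif schema == "sbh":
            for r in _rows(frame["cd"] > frame["ceb"]):
                report.add(path, r, "children dead exceeds children ever born")
            for r in _rows((frame[["women", "ceb", "cd"]] < 0).any(axis=1)):
                report.add(path, r, "negative count")
        elif schema == "estimates":
            for r in _rows(~((frame["q5"] > 0) & (frame["q5"] < 1))):
                report.add(path, r, "q5 outside (0, 1)")
            for r in _rows(frame["n"] < 3):
                report.add(path, r, "sample size below 3")
            if year_range is not None:
                lo, hi = year_range
                for r in _rows(~frame["year"].between(lo, hi)):
                    report.add(path, r, f"year outside [{lo}, {hi}]")
    return report


def write_cbh_csv(records, path, survey_id=None) -> None:
    from .records import records_to_frame
    frame = records_to_frame(records)
    if survey_id is not None:
        frame.insert(0, "survey_id", survey_id)
    frame.to_csv(path, index=False)


def write_sbh_csv(tables, path) -> None:
    """Write one or more SBHTable objects to the SBH CSV schema."""
    frames = []
    for t in tables:
        f = t.table.copy()
        f.insert(0, "grouping", t.grouping)
        f.insert(0, "county_id", t.county_id if t.county_id is not None else "")
        frames.append(f)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def load_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def dump_yaml(obj: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)
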