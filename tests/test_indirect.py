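import numpy as np
import pandas as pd
import pytest

from childmort.indirect import (CalibrationError, CohortCoefficients,
                                EmpiricalDistribution, PeriodCoefficients,
                                calibrate_coefficients, cohort_q5,
                                parity_ratios, period_q5, period_redistribute)
from childmort.records import MA_GROUPS, SBHTable
from childmort.validation import make_calibration_corpus


def sbh_from(parities=None, women=100, cd_frac=0.1, year=2010):
    """MA table with given mean parities per group."""
    parities = parities or {g: 1.0 for g in MA_GROUPS}
    rows = []
    for g in MA_GROUPS:
        ceb = int(round(parities.get(g, 1.0) * women))
        rows.append((g, women, ceb, int(round(cd_frac * ceb))))
    return SBHTable("MA", pd.DataFrame(rows, columns=["group_label", "women",
                                                      "ceb", "cd"]), year)


def test_parity_ratios_direct_division():
    sbh = sbh_from({"15-19": 0.2, "20-24": 1.0, "25-29": 2.5})
    r1, r2 = parity_ratios(sbh)
    assert r1 == pytest.approx(0.2)
    assert r2 == pytest.approx(0.4)


def test_parity_ratios_equal_parities():
    assert parity_ratios(sbh_from()) == (pytest.approx(1.0), pytest.approx(1.0))


def test_parity_ratio_zero_denominator():
    sbh = sbh_from({"20-24": 0.0})
    with pytest.raises(ZeroDivisionError):
        parity_ratios(sbh)


def test_identity_coefficients_return_raw_proportion():
    """With beta1 = 1 and all other coefficients zero the logit conversion
    is the identity: q5 = CD/CEB exactly."""
    sbh = sbh_from(cd_frac=0.15)
    coeffs = CohortCoefficients.identity("MA")
    out = cohort_q5(sbh, coeffs, parity_ratios(sbh))
    assert len(out) == 7
    for q5, _, g in out:
        row = sbh.row(g)
        assert q5 == pytest.approx(row["cd"] / row["ceb"], rel=1e-12)


def test_zero_cd_group_skipped():
    sbh = sbh_from()
    sbh.table.loc[sbh.table["group_label"] == "15-19", "cd"] = 0
    out = cohort_q5(sbh, CohortCoefficients.identity("MA"), (1.0, 1.0))
    assert "15-19" not in {g for _, _, g in out}
    assert len(out) == 6


def test_reference_years_decrease_with_age():
    sbh = sbh_from(cd_frac=0.1)
    out = cohort_q5(sbh, CohortCoefficients.identity("MA"), (1.0, 1.0))
    years = [y for _, y, _ in out]
    assert years == sorted(years, reverse=True)
    assert all(sbh.interview_year - 18 <= y <= sbh.interview_year for y in years)


def test_uniform_redistribution():
    sbh = SBHTable("MA", pd.DataFrame(
        [("20-24", 50, 100, 10)] + [(g, 0, 0, 0) for g in MA_GROUPS if g != "20-24"],
        columns=["group_label", "women", "ceb", "cd"]), 2010)
    dist = EmpiricalDistribution.uniform("MA", horizon=5)
    per_year = period_redistribute(sbh, dist)
    assert np.allclose(per_year["ceb"], 20.0)
    assert np.allclose(per_year["cd"], 2.0)


def test_redistribution_conserves_totals(rng):
    rows = [(g, 50, int(rng.integers(20, 200)), 0) for g in MA_GROUPS]
    rows = [(g, w, ceb, int(rng.integers(0, ceb // 3 + 1)))
            for g, w, ceb, _ in rows]
    sbh = SBHTable("MA", pd.DataFrame(rows, columns=["group_label", "women",
                                                     "ceb", "cd"]), 2010)
    horizon = 8
    dist = EmpiricalDistribution("MA", horizon)
    for g in MA_GROUPS:
        b = rng.random(horizon); d = rng.random(horizon)
        dist.births[g] = b / b.sum()
        dist.deaths[g] = d / d.sum()
    per_year = period_redistribute(sbh, dist)
    assert per_year["ceb"].sum() == pytest.approx(sbh.table["ceb"].sum(), abs=1e-9)
    assert per_year["cd"].sum() == pytest.approx(sbh.table["cd"].sum(), abs=1e-9)


def test_two_group_redistribution_hand_computed():
    sbh = SBHTable("MA", pd.DataFrame(
        [("20-24", 10, 40, 8), ("25-29", 10, 60, 6)]
        + [(g, 0, 0, 0) for g in MA_GROUPS if g not in ("20-24", "25-29")],
        columns=["group_label", "women", "ceb", "cd"]), 2010)
    dist = EmpiricalDistribution("MA", 2)
    for g in MA_GROUPS:
        dist.births[g] = np.array([0.5, 0.5])
        dist.deaths[g] = np.array([0.5, 0.5])
    dist.births["20-24"] = np.array([0.75, 0.25])
    dist.deaths["25-29"] = np.array([0.0, 1.0])
    per_year = period_redistribute(sbh, dist)
    # CEB: 40*(.75,.25) + 60*(.5,.5) = (60, 40); CD: 8*(.5,.5) + 6*(0,1) = (4, 10)
    assert per_year["ceb"].tolist() == [60.0, 40.0]
    assert per_year["cd"].tolist() == [4.0, 10.0]


def test_malformed_distribution_rejected():
    dist = EmpiricalDistribution.uniform("MA", horizon=5)
    dist.births["20-24"] = np.array([0.5, 0.2, 0.1, 0.1, 0.05])  # sums to 0.95
    sbh = sbh_from()
    with pytest.raises(ValueError, match="sums to"):
        period_redistribute(sbh, dist)


def test_period_identity_returns_raw_proportion():
    per_year = pd.DataFrame({"years_before": [0, 1, 2],
                             "ceb": [100.0, 80.0, 60.0],
                             "cd": [10.0, 12.0, 0.0]})
    out = period_q5(per_year, PeriodCoefficients.identity("MA"), 2010)
    # year with CD = 0 skipped
    assert len(out) == 2
    assert out[0] == (pytest.approx(0.10), 2010)
    assert out[1] == (pytest.approx(0.15), 2009)


def test_period_horizon_enforced():
    with pytest.raises(ValueError, match="horizon"):
        PeriodCoefficients("MA", pd.DataFrame(
            {"years_before": [30], "beta0": [0.0], "beta1": [1.0], "u": [0.0]}))


def test_calibration_requires_varied_corpus():
    """Twenty bit-identical surveys leave every regressor constant, which
    must be reported as a degenerate design, not silently fitted."""
    corpus, _ = make_calibration_corpus(1, women_per_survey=400, seed=9)
    with pytest.raises(CalibrationError, match="no variation|at least 20"):
        calibrate_coefficients(corpus * 20)


def test_calibration_small_corpus_rejected():
    corpus, _ = make_calibration_corpus(3, women_per_survey=200, seed=1)
    with pytest.raises(CalibrationError, match="at least 20"):
        calibrate_coefficients(corpus)
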