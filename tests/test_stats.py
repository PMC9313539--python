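"""Nonparametric cohort statistics and the published-value regressions."""

import numpy as np
import pytest
import scipy.stats

from spinequant.stats import (cohort_report, exclude_fractured, friedman,
                              mann_whitney, median_iqr, patient_medians,
                              pooled_group_summary, reproduce_table1,
                              round_half_away, spearman)


def test_exclude_fractured_counts(table1):
    sub = exclude_fractured(table1)
    assert len(sub) == 23
    assert not sub.fractured.any()
    none_flagged = table1.assign(fractured=False)
    assert len(exclude_fractured(none_flagged)) == 28


@pytest.mark.parametrize("values, expected", [
    ([46.0, 49.4], (47.7, 46.85, 48.55)),
    ([29731, 29447, 22665, 50760], (29589.0, 27751.5, 34988.25)),
    ([5, 5, 5], (5.0, 5.0, 5.0)),
])
def test_median_iqr_convention(values, expected):
    """Quartiles interpolate order statistics at positions 1 + (n-1)p."""
    assert median_iqr(values) == pytest.approx(expected)


def test_median_iqr_empty_raises():
    with pytest.raises(ValueError):
        median_iqr([])


def test_pooled_group_summaries(table1):
    gs = pooled_group_summary(table1, "metastasis", "pdff_percent")
    assert round_half_away(gs.median, 1) == 11.9
    assert gs.n == 12
    gs = pooled_group_summary(table1, "osteoporosis", "failure_load_N")
    assert round_half_away(gs.median, 0) == 3095
    assert gs.n == 11
    with pytest.raises(ValueError):
        pooled_group_summary(table1, "no-such-group", "pdff_percent")


def test_patient_medians(table1):
    pm = patient_medians(table1, "pdff_percent")
    assert [round_half_away(v, 1) for v in pm] == [
        27.0, 9.9, 9.3, 47.7, 38.0, 42.4, 44.7]
    pd_ = patient_medians(table1, "failure_displacement_mm")
    assert pd_[5] == pytest.approx(0.348)


def test_mann_whitney_full_separation():
    """3-vs-4 complete separation: U = 0 and asymptotic p = 0.034."""
    r = mann_whitney([9.9, 9.3, 27.0], [47.7, 38.0, 42.4, 44.7])
    assert r.statistic == 0.0
    assert round(r.p_two_sided, 3) == 0.034
    assert r.extra["z"] == pytest.approx(-6 / np.sqrt(8))


def test_mann_whitney_identical_groups():
    r = mann_whitney([1, 2, 3], [1, 2, 3])
    assert r.extra["z"] == pytest.approx(0.0)
    assert r.p_two_sided == pytest.approx(1.0)
    with pytest.raises(ValueError):
        mann_whitney([], [1.0])


def test_mann_whitney_matches_brute_force_pair_count():
    """U equals the number of cross-group pairs won (brute force oracle)."""
    rng = np.random.default_rng(123)
    for _ in range(200):
        n1, n2 = rng.integers(2, 8, 2)
        a = rng.integers(0, 10, n1).astype(float)  # ties included
        b = rng.integers(0, 10, n2).astype(float)
        r = mann_whitney(a, b)
        wins_b = sum((x > y) + 0.5 * (x == y) for x in a for y in b)
        u1 = n1 * n2 - wins_b
        assert min(u1, n1 * n2 - u1) == pytest.approx(r.statistic)


def test_spearman_fixture_correlations(table1):
    """rho is an exact rational on the patient medians:
    1 - 6*106/336 = -25/28 and 1 - 6*94/336 = -19/28."""
    pdff = patient_medians(table1, "pdff_percent")
    load = patient_medians(table1, "failure_load_N")
    disp = patient_medians(table1, "failure_displacement_mm")
    r_load = spearman(pdff, load)
    assert r_load.statistic == pytest.approx(-25 / 28, abs=1e-12)
    assert round(r_load.p_two_sided, 3) == 0.007
    assert r_load.ci_low == pytest.approx(-0.984, abs=0.005)
    assert r_load.ci_high == pytest.approx(-0.427, abs=0.005)
    r_disp = spearman(pdff, disp)
    assert r_disp.statistic == pytest.approx(-19 / 28, abs=1e-12)
    assert round(r_disp.p_two_sided, 3) == 0.094
    assert r_disp.ci_low == pytest.approx(-0.947, abs=0.005)
    assert r_disp.ci_high == pytest.approx(0.152, abs=0.005)


def test_spearman_antitone_and_validation():
    r = spearman([1, 2, 3, 4], [8, 6, 4, 2])
    assert r.statistic == pytest.approx(-1.0)
    with pytest.raises(ValueError):
        spearman([1, 2], [3, 4])


def test_spearman_matches_scipy():
    rng = np.random.default_rng(7)
    for _ in range(25):
        x = rng.normal(size=9)
        y = rng.normal(size=9) + 0.5 * x
        mine = spearman(x, y)
        ref_rho, ref_p = scipy.stats.spearmanr(x, y)
        assert mine.statistic == pytest.approx(ref_rho, abs=1e-12)
        assert mine.p_two_sided == pytest.approx(ref_p, rel=1e-6)


def test_friedman_constant_blocks(table1):
    t = table1.copy()
    t["pdff_percent"] = 1.0
    t["fractured"] = False
    r = friedman(t, "pdff_percent")
    assert r.statistic == 0.0 and r.p_two_sided == 1.0


def test_friedman_identical_order_statistic():
    """k=4 levels in identical order for b=3 patients: chi2 = 9 by the
    rank-sum formula (independently recomputed)."""
    import pandas as pd

    rows = []
    for pid in range(3):
        for j, lev in enumerate(("L1", "L2", "L3", "L4")):
            rows.append({"patient_id": pid, "group": "g", "level": lev,
                         "fractured": False, "m": float(j + pid * 0.01)})
    t = pd.DataFrame(rows)
    r = friedman(t, "m")
    b, k = 3, 4
    ranks = np.tile(np.arange(1, k + 1), (b, 1))
    col = ranks.sum(axis=0)
    expected = 12.0 / (b * k * (k + 1)) * np.sum(col**2) - 3 * b * (k + 1)
    assert r.statistic == pytest.approx(expected) == pytest.approx(9.0)


def test_friedman_matches_scipy_on_fixture(table1):
    """Cross-check the metastasis-group PDFF test against scipy."""
    sub = table1[table1.group == "metastasis"]
    mine = friedman(table1, "pdff_percent", "metastasis")
    wide = sub.pivot(index="patient_id", columns="level",
                     values="pdff_percent")
    ref = scipy.stats.friedmanchisquare(*[wide[c] for c in wide.columns])
    assert mine.statistic == pytest.approx(ref.statistic, rel=1e-12)
    assert mine.p_two_sided == pytest.approx(ref.pvalue, rel=1e-9)
    assert mine.extra["blocks"] == 3


def test_friedman_needs_complete_blocks(table1):
    with pytest.raises(ValueError):
        friedman(table1, "pdff_percent", "osteoporosis")  # only ID7 complete


def test_round_half_away():
    assert round_half_away(11.85, 1) == 11.9
    assert round_half_away(-11.85, 1) == -11.9
    assert round_half_away(2981.5) == 2982.0


def test_reproduce_table1_regression():
    df = reproduce_table1()
    assert len(df) == 21 * 3 + 6 * 3
    assert df.ok.all(), df[~df.ok].to_string()


def test_cohort_report_structure(table1):
    rep = cohort_report(table1)
    for m in ("pdff_percent", "failure_displacement_mm", "failure_load_N"):
        assert round(rep["mann_whitney"][m].p_two_sided, 3) == 0.034
    assert round(rep["spearman"]["pdff_percent~failure_load_N"].statistic,
                 3) == -0.893
    assert "metastasis:pdff_percent" in rep["friedman"]
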