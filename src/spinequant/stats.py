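"""Nonparametric cohort statistics for the per-vertebra measurement table.

Conventions follow the SPSS analyses the published numbers came from:

- quartiles by linear interpolation between order statistics at positions
  1 + (n - 1) p (numpy's 'linear' percentile method);
- Mann-Whitney U with the asymptotic normal approximation, no continuity
  correction, tie-corrected variance;
- Spearman's rho as the Pearson correlation of (average) ranks, p from the
  t approximation on n - 2 df, 95% CI by Fisher z-transform with standard
  error 1 / sqrt(n - 3);
- Friedman's chi-square over within-patient level ranks, tie-corrected.

Fractured vertebrae are excluded before any averaging or testing. Group
tests run on patient-level medians; descriptive group summaries pool all
non-fractured vertebrae.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm, rankdata
from scipy.stats import t as t_dist

from .fixtures import (MEASURE_DECIMALS, MEASURES, PRINTED_PATIENT_SUMMARY,
                       PRINTED_POOLED, table1_fixture)

__all__ = [
    "GroupSummary",
    "TestResult",
    "exclude_fractured",
    "median_iqr",
    "pooled_group_summary",
    "patient_medians",
    "mann_whitney",
    "spearman",
    "friedman",
    "round_half_away",
    "reproduce_table1",
    "cohort_report",
]

logger = logging.getLogger(__name__)


@dataclass
class GroupSummary:
    group: str
    n: int
    median: float
    q1: float
    q3: float


@dataclass
class TestResult:
    statistic: float
    p_two_sided: float
    method: str
    ci_low: float = math.nan
    ci_high: float = math.nan
    extra: dict = None


def exclude_fractured(table: pd.DataFrame) -> pd.DataFrame:
    """Drop rows flagged as fractured; the removal count is logged."""
    n_removed = int(table["fractured"].sum())
    out = table.loc[~table["fractured"]].reset_index(drop=True)
    logger.info("excluded %d fractured vertebrae (%d remain)", n_removed, len(out))
    kept_patients = set(out["patient_id"])
    lost = set(table["patient_id"]) - kept_patients
    if lost:
        logger.warning("patients fully excluded by fracture flags: %s", sorted(lost))
    return out


def median_iqr(values) -> tuple[float, float, float]:
    """(median, Q1, Q3) with quartiles interpolated at 1 + (n - 1) p."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("median_iqr needs at least one value")
    q1, med, q3 = np.percentile(v, [25, 50, 75], method="linear")
    return float(med), float(q1), float(q3)


def pooled_group_summary(table: pd.DataFrame, group: str,
                         measure: str) -> GroupSummary:
    """Median/IQR over all non-fractured vertebrae of one group, pooled."""
    sub = exclude_fractured(table)
    vals = sub.loc[sub["group"] == group, measure].to_numpy()
    if len(vals) == 0:
        raise ValueError(f"no non-fractured vertebrae in group {group!r}")
    med, q1, q3 = median_iqr(vals)
    return GroupSummary(group, len(vals), med, q1, q3)


def patient_medians(table: pd.DataFrame, measure: str) -> pd.Series:
    """Per-patient median over non-fractured L1-L4, ordered by patient id."""
    sub = exclude_fractured(table)
    return sub.groupby("patient_id")[measure].median().sort_index()


def mann_whitney(a, b) -> TestResult:
    """Asymptotic Mann-Whitney U test, no continuity correction.

    z = (U - n1 n2 / 2) / sqrt(var) with the tie-corrected variance; the
    reported statistic is min(U1, U2).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    r1 = ranks[:n1].sum()
    u1 = n1 * n2 + n1 * (n1 + 1) / 2.0 - r1
    u2 = n1 * n2 - u1
    u = min(u1, u2)
    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return TestResult(u, 1.0, "mann-whitney-asymptotic", extra={"z": 0.0})
    z = (u - n1 * n2 / 2.0) / math.sqrt(var)
    p = 2.0 * norm.sf(abs(z))
    return TestResult(u, min(p, 1.0), "mann-whitney-asymptotic",
                      extra={"z": z, "U1": u1, "U2": u2})


def spearman(x, y) -> TestResult:
    """Spearman's rho with t-approximation p and Fisher-z 95% CI."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired samples of equal length >= 3")
    n = len(x)
    rx, ry = rankdata(x), rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
        p = 2.0 * t_dist.sf(abs(t), n - 2)
    if n > 3 and abs(rho) < 1.0:
        zr = math.atanh(rho)
        half = norm.ppf(0.975) / math.sqrt(n - 3)
        lo, hi = math.tanh(zr - half), math.tanh(zr + half)
    else:
        lo = hi = math.nan
    return TestResult(rho, p, "spearman-t", ci_low=lo, ci_high=hi)


def friedman(table: pd.DataFrame, measure: str,
             group: str | None = None) -> TestResult:
    """Friedman's two-way ANOVA by ranks across vertebral levels.

    Blocks are patients; treatments are levels L1-L4. Patients with an
    incomplete level set (e.g. after fracture exclusion) are dropped with a
    warning. Tie-corrected chi-square statistic on k - 1 df.
    """
    sub = exclude_fractured(table)
    if group is not None:
        sub = sub.loc[sub["group"] == group]
    wide = sub.pivot(index="patient_id", columns="level", values=measure)
    complete = wide.dropna()
    n_dropped = len(wide) - len(complete)
    if n_dropped:
        logger.warning("friedman: dropped %d incomplete patients", n_dropped)
    b, k = complete.shape
    if b < 2 or k < 2:
        raise ValueError("friedman needs >= 2 complete patients and >= 2 levels")
    r = np.apply_along_axis(rankdata, 1, complete.to_numpy())
    col_sums = r.sum(axis=0)
    mean_rank = b * (k + 1) / 2.0
    a = (r**2).sum()
    c = b * k * (k + 1) ** 2 / 4.0
    if a == c:  # all blocks constant: no variation in ranks
        return TestResult(0.0, 1.0, "friedman", extra={"df": k - 1, "blocks": b})
    stat = (k - 1) * float(((col_sums - mean_rank) ** 2).sum()) / (a - c)
    p = float(chi2.sf(stat, k - 1))
    return TestResult(stat, p, "friedman", extra={"df": k - 1, "blocks": b})


def round_half_away(x: float, decimals: int = 0) -> float:
    """Round half away from zero (the convention of the printed tables)."""
    factor = 10.0**decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def reproduce_table1(tolerance_ulp: float = 1.0) -> pd.DataFrame:
    """Regression of every published median [Q1-Q3] cell against this code.

    Recomputes the 21 patient-level cells and the 6 pooled group cells from
    the fixture and compares with the printed values. ``tolerance_ulp`` is
    the allowed deviation in units of the last printed digit: the printed
    per-level inputs are themselves rounded, so interpolated quartiles can
    legitimately differ from the printed bracket by up to one final digit.
    """
    table = table1_fixture()
    sub = exclude_fractured(table)
    rows = []
    for pid, printed in PRINTED_PATIENT_SUMMARY.items():
        vals = sub.loc[sub["patient_id"] == pid]
        for measure in MEASURES:
            dec = MEASURE_DECIMALS[measure]
            med, q1, q3 = median_iqr(vals[measure].to_numpy())
            for stat_name, comp, ref in (("median", med, printed[measure][0]),
                                         ("q1", q1, printed[measure][1]),
                                         ("q3", q3, printed[measure][2])):
                ulp = abs(comp - ref) * 10.0**dec
                rows.append({"scope": f"patient {pid}", "measure": measure,
                             "stat": stat_name,
                             "computed": round_half_away(comp, dec),
                             "printed": ref, "deviation_ulp": ulp,
                             "ok": ulp <= tolerance_ulp + 1e-9})
    for grp, printed in PRINTED_POOLED.items():
        for measure in MEASURES:
            dec = MEASURE_DECIMALS[measure]
            gs = pooled_group_summary(table, grp, measure)
            for stat_name, comp, ref in (("median", gs.median, printed[measure][0]),
                                         ("q1", gs.q1, printed[measure][1]),
                                         ("q3", gs.q3, printed[measure][2])):
                ulp = abs(comp - ref) * 10.0**dec
                rows.append({"scope": f"pooled {grp}", "measure": measure,
                             "stat": stat_name,
                             "computed": round_half_away(comp, dec),
                             "printed": ref, "deviation_ulp": ulp,
                             "ok": ulp <= tolerance_ulp + 1e-9})
    return pd.DataFrame(rows)


def cohort_report(table: pd.DataFrame) -> dict:
    """Full statistical stage on one cohort table.

    Pooled group summaries, patient-level medians, Mann-Whitney group
    comparisons on patient medians, Spearman correlations of PDFF with the
    two failure measures, and per-group Friedman tests across levels where
    enough complete patients remain.
    """
    groups = sorted(table["group"].unique())
    out = {"group_summaries": {}, "patient_medians": {}, "mann_whitney": {},
           "spearman": {}, "friedman": {}}
    for g in groups:
        for m in MEASURES:
            gs = pooled_group_summary(table, g, m)
            out["group_summaries"][f"{g}:{m}"] = gs
    pm = {m: patient_medians(table, m) for m in MEASURES}
    out["patient_medians"] = pm
    if len(groups) == 2:
        sub = exclude_fractured(table)
        gmap = sub.drop_duplicates("patient_id").set_index("patient_id")["group"]
        for m in MEASURES:
            a = pm[m][gmap == groups[0]]
            b = pm[m][gmap == groups[1]]
            out["mann_whitney"][m] = mann_whitney(a, b)
    for m in ("failure_displacement_mm", "failure_load_N"):
        out["spearman"][f"pdff_percent~{m}"] = spearman(
            pm["pdff_percent"].to_numpy(), pm[m].to_numpy())
    for g in groups:
        for m in MEASURES:
            try:
                out["friedman"][f"{g}:{m}"] = friedman(table, m, g)
            except ValueError:
                pass
    return out
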