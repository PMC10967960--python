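"""Cohort-level statistics for longitudinal OCT measures.

The study design compares two steroid-induced glaucoma cohorts (MsDx,
MsDxF) against healthy controls across a fixed visit grid of weeks
{0, 2, 4, 6, 8, 12, 18, 24}, with IOP and OCT-derived vitreous measures per
(animal, eye, week).  This module provides the statistical layer:
Kolmogorov–Smirnov normality checks, one-way ANOVA per timepoint with
Bonferroni-adjusted pairwise comparisons, and (possibly lagged) Pearson
correlations between measures at different weeks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError

STUDY_WEEKS = (0, 2, 4, 6, 8, 12, 18, 24)
COHORTS = ("MsDx", "MsDxF", "control")
ALPHA = 0.05

#: |r| thresholds for the strength labels
WEAK_MODERATE_R = 0.4
MODERATE_STRONG_R = 0.7


def make_cohort_table(
    summary_table: pd.DataFrame, iop_table: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Join per-eye summaries with IOP into a long table keyed by (animal, eye, week).

    Validates key uniqueness and that weeks lie on the study grid.
    """
    df = summary_table.copy()
    if iop_table is not None:
        df = df.merge(iop_table, on=["animal", "eye", "week"], how="left")
    keys = ["animal", "eye", "week"]
    if df.duplicated(subset=keys).any():
        raise ValueError("duplicate (animal, eye, week) rows in cohort table")
    if df["week"].isna().any():
        raise ValueError("rows missing week metadata; set eye_meta when analysing stacks")
    bad = set(df["week"].unique()) - set(STUDY_WEEKS)
    if bad:
        raise ValueError(f"weeks outside the study grid {STUDY_WEEKS}: {sorted(bad)}")
    return df


def normality_test(values) -> tuple[float, float]:
    """One-sample Kolmogorov–Smirnov test against N(sample mean, sample SD).

    Raises :class:`InsufficientDataError` for n < 5 or a constant sample.
    """
    vals = np.asarray(values, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size < 5:
        raise InsufficientDataError(f"normality test needs n >= 5, got {vals.size}")
    sd = vals.std(ddof=1)
    if sd <= 0:
        raise InsufficientDataError("constant sample: variance is zero")
    res = stats.kstest(vals, "norm", args=(vals.mean(), sd))
    return float(res.statistic), float(res.pvalue)


def bonferroni(p: float | np.ndarray, m: int) -> float | np.ndarray:
    """Bonferroni adjustment: min(1, m·p); never decreases a p-value."""
    if m < 1:
        raise ValueError("number of comparisons must be >= 1")
    return np.minimum(1.0, np.asarray(p, dtype=float) * m)[()]


@dataclass
class PairwiseComparison:
    group_a: str
    group_b: str
    t: float
    p_raw: float
    p_adjusted: float
    significant: bool


@dataclass
class AnovaResult:
    response: str
    week: int | None
    f: float
    p: float
    groups: list[str]
    group_n: dict[str, int]
    pairwise: list[PairwiseComparison]


def groupwise_anova(
    table: pd.DataFrame,
    response: str,
    group: str = "cohort",
    week: int | None = None,
    alpha: float = ALPHA,
) -> AnovaResult:
    """One-way ANOVA across cohorts at one week, with Bonferroni post-hocs.

    Pairwise comparisons use Welch t-tests (robust to unequal group sizes),
    each adjusted by the number of pairs.  Groups with fewer than 2
    observations are dropped with a warning; fewer than 2 usable groups is
    an error.  Identical values in every group return F = 0, p = 1.
    """
    df = table if week is None else table[table["week"] == week]
    samples: dict[str, np.ndarray] = {}
    for g, sub in df.groupby(group, observed=True):
        vals = np.asarray(sub[response].dropna(), dtype=float)
        if len(vals) < 2:
            warnings.warn(f"group {g!r} has <2 observations at week {week}; dropped")
            continue
        samples[str(g)] = vals
    if len(samples) < 2:
        raise InsufficientDataError("fewer than 2 groups with >= 2 observations")

    names = sorted(samples)
    arrays = [samples[g] for g in names]
    grand = np.concatenate(arrays)
    if np.ptp(grand) == 0:  # all values identical: 0/0 F-statistic by convention
        f_stat, p_val = 0.0, 1.0
    else:
        res = stats.f_oneway(*arrays)
        f_stat, p_val = float(res.statistic), float(res.pvalue)
        if not np.isfinite(f_stat):  # zero within-group variance, equal means
            f_stat, p_val = 0.0, 1.0

    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    m = len(pairs)
    pairwise = []
    for a, b in pairs:
        t_res = stats.ttest_ind(samples[a], samples[b], equal_var=False)
        p_adj = float(bonferroni(float(t_res.pvalue), m))
        pairwise.append(
            PairwiseComparison(
                group_a=a,
                group_b=b,
                t=float(t_res.statistic),
                p_raw=float(t_res.pvalue),
                p_adjusted=p_adj,
                significant=p_adj < alpha,
            )
        )
    return AnovaResult(
        response=response,
        week=week,
        f=f_stat,
        p=p_val,
        groups=names,
        group_n={g: len(samples[g]) for g in names},
        pairwise=pairwise,
    )


@dataclass
class CorrelationResult:
    x_label: str
    y_label: str
    r: float
    p: float
    n: int
    strength: str


def correlation_strength(r: float) -> str:
    """Conventional strength label: |r| < 0.4 weak, 0.4–0.7 moderate, > 0.7 strong."""
    mag = abs(r)
    if mag < WEAK_MODERATE_R:
        label = "weak"
    elif mag <= MODERATE_STRONG_R:
        label = "moderate"
    else:
        label = "strong"
    return f"inverse {label}" if r < 0 else label


def lagged_correlations(
    table: pd.DataFrame,
    var_x: tuple[str, int],
    var_y: tuple[str, int],
    cohort: str | None = None,
    sex: str | None = None,
    eye: str | None = None,
) -> CorrelationResult:
    """Pearson correlation between one measure@week and another measure@week.

    Observations are paired on (animal, eye); an animal-eye enters only if it
    has both measurements.  Optional subgroup filters restrict cohort, sex
    and eye side.  Needs >= 3 pairs and non-degenerate variance.
    """
    df = table
    for col, val in (("cohort", cohort), ("sex", sex), ("eye", eye)):
        if val is not None:
            df = df[df[col] == val]

    def _pivot(measure: str, week: int) -> pd.Series:
        sub = df[df["week"] == week]
        return sub.set_index(["animal", "eye"])[measure]

    sx = _pivot(*var_x)
    sy = _pivot(*var_y)
    joined = pd.concat([sx.rename("x"), sy.rename("y")], axis=1, join="inner").dropna()
    n = len(joined)
    if n < 3:
        raise InsufficientDataError(f"need >= 3 paired observations, got {n}")
    x = joined["x"].to_numpy(dtype=float)
    y = joined["y"].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise InsufficientDataError("zero variance: correlation undefined")
    res = stats.pearsonr(x, y)
    r, p = float(res.statistic), float(res.pvalue)
    return CorrelationResult(
        x_label=f"{var_x[0]}@w{var_x[1]}",
        y_label=f"{var_y[0]}@w{var_y[1]}",
        r=r,
        p=p,
        n=n,
        strength=correlation_strength(r),
    )


def anova_table(
    table: pd.DataFrame, responses: list[str], weeks: list[int] | None = None
) -> pd.DataFrame:
    """Tidy ANOVA results per (measure, week), one row per pairwise comparison."""
    weeks = weeks or sorted(table["week"].unique())
    rows = []
    for resp in responses:
        for wk in weeks:
            try:
                res = groupwise_anova(table, resp, week=wk)
            except InsufficientDataError:
                continue
            for pc in res.pairwise:
                rows.append(
                    {
                        "measure": resp,
                        "week": wk,
                        "F": res.f,
                        "p_anova": res.p,
                        "pair": f"{pc.group_a}-{pc.group_b}",
                        "t": pc.t,
                        "p_raw": pc.p_raw,
                        "p_bonferroni": pc.p_adjusted,
                        "significant": pc.significant,
                    }
                )
    return pd.DataFrame(rows)
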