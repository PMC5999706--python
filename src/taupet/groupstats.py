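"""Group comparisons on SUVR tables.

Percent differences, Cohen's d (pooled-SD form), unpaired/paired Student
t-tests (also from printed summary statistics), longitudinal percent
change, and Pearson correlation for PET-histology validation.

Conventions: two-tailed tests throughout; the unpaired test is the
pooled-variance Student test (Welch available via ``welch=True``); a
degenerate comparison with zero pooled SD and equal means returns
``t = 0, p = 1`` rather than raising.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .petquant import SUVRRecord

__all__ = [
    "GroupComparison",
    "LongitudinalChange",
    "percent_difference",
    "cohens_d",
    "cohens_d_from_summary",
    "ttest_from_summary",
    "unpaired_ttest",
    "paired_ttest",
    "longitudinal_change",
    "pearson_correlation",
    "compare_groups",
    "suvr_group_table",
]


@dataclass(frozen=True)
class GroupComparison:
    """TG-vs-WT summary for one tracer/session cell."""

    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    percent_diff: float
    percent_diff_rounded: int
    cohens_d: float
    t: float
    df: float
    p: float


@dataclass(frozen=True)
class LongitudinalChange:
    """Baseline-to-follow-up percent change on matched animals."""

    animal_ids: tuple[str, ...]
    percent_change: np.ndarray  # per animal
    mean: float
    sd: float
    t: float
    df: float
    p: float


def percent_difference(mean_a: float, mean_b: float) -> float:
    """100 * (mean_a - mean_b) / mean_b (report rounded alongside)."""
    if mean_b <= 0:
        raise ValueError("reference mean must be positive")
    return 100.0 * (mean_a - mean_b) / mean_b


def _pooled_sd(sd_a: float, n_a: int, sd_b: float, n_b: int) -> float:
    return float(
        np.sqrt(((n_a - 1) * sd_a**2 + (n_b - 1) * sd_b**2) / (n_a + n_b - 2))
    )


def cohens_d(values_a: Sequence[float], values_b: Sequence[float]) -> float:
    """Standardized mean difference using the pooled SD."""
    a, b = np.asarray(values_a, float), np.asarray(values_b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    return cohens_d_from_summary(a.mean(), a.std(ddof=1), a.size, b.mean(), b.std(ddof=1), b.size)


def cohens_d_from_summary(
    mean_a: float, sd_a: float, n_a: int, mean_b: float, sd_b: float, n_b: int
) -> float:
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs n >= 2")
    sp = _pooled_sd(sd_a, n_a, sd_b, n_b)
    if sp == 0:
        if mean_a == mean_b:
            return 0.0
        raise ValueError("zero pooled SD with unequal means: d undefined")
    return float((mean_a - mean_b) / sp)


def ttest_from_summary(
    mean_a: float,
    sd_a: float,
    n_a: int,
    mean_b: float,
    sd_b: float,
    n_b: int,
    welch: bool = False,
) -> tuple[float, float, float]:
    """Two-sample t-test from group summaries; returns (t, df, p)."""
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs n >= 2")
    if sd_a < 0 or sd_b < 0:
        raise ValueError("SDs must be non-negative")
    if sd_a == 0 and sd_b == 0:
        if mean_a == mean_b:
            return 0.0, float(n_a + n_b - 2), 1.0
        raise ValueError("zero variance in both groups with unequal means")
    res = stats.ttest_ind_from_stats(
        mean_a, sd_a, n_a, mean_b, sd_b, n_b, equal_var=not welch
    )
    df = (n_a + n_b - 2) if not welch else _welch_df(sd_a, n_a, sd_b, n_b)
    return float(res.statistic), float(df), float(res.pvalue)


def _welch_df(sd_a, n_a, sd_b, n_b) -> float:
    va, vb = sd_a**2 / n_a, sd_b**2 / n_b
    return (va + vb) ** 2 / (va**2 / (n_a - 1) + vb**2 / (n_b - 1))


def unpaired_ttest(
    values_a: Sequence[float], values_b: Sequence[float], welch: bool = False
) -> tuple[float, float, float]:
    a, b = np.asarray(values_a, float), np.asarray(values_b, float)
    return ttest_from_summary(
        a.mean(), a.std(ddof=1), a.size, b.mean(), b.std(ddof=1), b.size, welch=welch
    )


def paired_ttest(before: Sequence[float], after: Sequence[float]) -> tuple[float, float, float]:
    a, b = np.asarray(before, float), np.asarray(after, float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    if a.size < 2:
        raise ValueError("paired test needs n >= 2")
    d = b - a
    if np.all(d == 0):
        return 0.0, float(a.size - 1), 1.0
    if d.std(ddof=1) == 0:
        raise ValueError("paired differences have zero SD (all equal, nonzero)")
    res = stats.ttest_rel(b, a)
    return float(res.statistic), float(a.size - 1), float(res.pvalue)


def compare_groups(values_a: Sequence[float], values_b: Sequence[float]) -> GroupComparison:
    """Full TG-vs-WT record: means, SDs, delta-%, d, pooled t, p."""
    a, b = np.asarray(values_a, float), np.asarray(values_b, float)
    pct = percent_difference(a.mean(), b.mean())
    t, df, p = unpaired_ttest(a, b)
    return GroupComparison(
        mean_a=float(a.mean()),
        sd_a=float(a.std(ddof=1)),
        n_a=int(a.size),
        mean_b=float(b.mean()),
        sd_b=float(b.std(ddof=1)),
        n_b=int(b.size),
        percent_diff=float(pct),
        percent_diff_rounded=int(round(pct)),
        cohens_d=cohens_d(a, b),
        t=t,
        df=df,
        p=p,
    )


def longitudinal_change(
    baseline: Mapping[str, float], followup: Mapping[str, float]
) -> LongitudinalChange:
    """Per-animal percent change on animals with both timepoints.

    Animals missing either scan are excluded pairwise.  The paired t-test
    is run on the baseline vs follow-up values themselves.
    """
    ids = sorted(set(baseline) & set(followup))
    if not ids:
        raise ValueError("no animals with both baseline and follow-up values")
    bl = np.array([baseline[i] for i in ids], float)
    fu = np.array([followup[i] for i in ids], float)
    if np.any(bl <= 0):
        raise ValueError("baseline values must be positive for percent change")
    pct = 100.0 * (fu - bl) / bl
    if len(ids) >= 2:
        t, df, p = paired_ttest(bl, fu)
        sd = float(pct.std(ddof=1))
    else:
        t, df, p, sd = float("nan"), 0.0, float("nan"), float("nan")
    return LongitudinalChange(tuple(ids), pct, float(pct.mean()), sd, t, df, p)


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson R with the two-tailed p from the t transform (df = n - 2)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1D vectors")
    if x.size < 3:
        raise ValueError("correlation needs n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant input: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def suvr_group_table(records: Sequence[SUVRRecord]) -> pd.DataFrame:
    """Result-overview table: one row per tracer, TG vs WT comparison.

    Input records should belong to a single session; columns mirror a
    demographics/result-overview layout (group means +/- SD, n, delta-%,
    Cohen's d, t, p).
    """
    df = pd.DataFrame(
        [
            {
                "tracer": r.tracer,
                "genotype": r.genotype,
                "animal_id": r.animal_id,
                "suvr": r.value,
            }
            for r in records
        ]
    )
    rows = []
    for tracer, sub in df.groupby("tracer", sort=True):
        tg = sub.loc[sub.genotype == "TG", "suvr"].to_numpy()
        wt = sub.loc[sub.genotype == "WT", "suvr"].to_numpy()
        gc = compare_groups(tg, wt)
        rows.append(
            {
                "tracer": tracer,
                "mean_tg": gc.mean_a,
                "sd_tg": gc.sd_a,
                "n_tg": gc.n_a,
                "mean_wt": gc.mean_b,
                "sd_wt": gc.sd_b,
                "n_wt": gc.n_b,
                "percent_diff": gc.percent_diff,
                "percent_diff_rounded": gc.percent_diff_rounded,
                "cohens_d": gc.cohens_d,
                "t": gc.t,
                "df": gc.df,
                "p": gc.p,
            }
        )
    return pd.DataFrame(rows)
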