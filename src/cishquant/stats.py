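"""Group comparisons and grade/OD concordance.

Group contrasts use the two-sample t-test with unequal variances (Welch),
with Welch-Satterthwaite degrees of freedom and two-tailed p-values, run at
the sample level: technical replicates are averaged to one value per sample
first, so triplicates never inflate the effective n.  All 15 unordered
pairs of the six study groups are compared for each requested metric.  Raw
pairwise p-values are reported (matching the study's convention of no
multiplicity correction) together with a Holm-adjusted column for modern
use.

Concordance between the ordinal visual grade and the spectral OD is
summarized both ways the field quotes it: Spearman's rank correlation
(mid-rank ties) and the OLS slope of OD on grade code with its two-tailed
slope test.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, InsufficientDataError, ParameterError

__all__ = [
    "GroupComparison",
    "ConcordanceResult",
    "welch_t_test",
    "compare_all_groups",
    "comparisons_to_frame",
    "grade_od_concordance",
]


@dataclass
class GroupComparison:
    """One Welch comparison of one metric between two groups."""

    metric_name: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    t_stat: float
    df: float
    p_two_tailed: float
    significant: bool
    p_holm: float | None = None


def welch_t_test(a: Sequence[float], b: Sequence[float]) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test; returns ``(t, df, p_two_tailed)``.

    ``t = (mean_a - mean_b) / sqrt(s2_a/n_a + s2_b/n_b)`` with sample
    variances on ``n - 1`` denominators and Welch-Satterthwaite df.  If both
    groups have zero variance and equal means the test is vacuous and
    ``(0, n_a + n_b - 2, 1)`` is returned by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("each group needs >= 2 values")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ParameterError("group values must be finite")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, float(a.size + b.size - 2), 1.0
        raise InsufficientDataError("both groups have zero variance with unequal means")
    res = sps.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def compare_all_groups(
    metrics_table: pd.DataFrame,
    metric_names: Sequence[str],
    alpha: float = 0.05,
    group_col: str = "group",
    sample_col: str = "sample_id",
) -> list[GroupComparison]:
    """All pairwise Welch comparisons of every metric between every group.

    ``metrics_table`` has one row per sample-replicate; replicates are
    averaged to the sample level before testing.  Returns one
    :class:`GroupComparison` per (metric, unordered group pair), each
    flagged at ``alpha`` on the raw p and carrying a Holm-adjusted p
    computed across the pairs of its metric.
    """
    if not (0 < alpha < 1):
        raise ParameterError("alpha must lie in (0, 1)")
    for m in metric_names:
        if m not in metrics_table.columns:
            raise ConfigurationError(f"unknown metric {m!r}")
    per_sample = (
        metrics_table.groupby([sample_col, group_col], sort=True)[list(metric_names)]
        .mean()
        .reset_index()
    )
    groups = sorted(per_sample[group_col].unique())
    if len(groups) < 2:
        raise InsufficientDataError("need >= 2 groups to compare")

    out: list[GroupComparison] = []
    for metric in metric_names:
        batch: list[GroupComparison] = []
        for ga, gb in combinations(groups, 2):
            va = per_sample.loc[per_sample[group_col] == ga, metric].dropna().to_numpy()
            vb = per_sample.loc[per_sample[group_col] == gb, metric].dropna().to_numpy()
            t, df, p = welch_t_test(va, vb)
            batch.append(GroupComparison(
                metric_name=metric, group_a=ga, group_b=gb,
                n_a=va.size, n_b=vb.size,
                mean_a=float(va.mean()), mean_b=float(vb.mean()),
                t_stat=t, df=df, p_two_tailed=p,
                significant=bool(p < alpha),
            ))
        holm = multipletests([c.p_two_tailed for c in batch], method="holm")[1]
        for c, ph in zip(batch, holm):
            c.p_holm = float(ph)
        out.extend(batch)
    return out


def comparisons_to_frame(comparisons: Sequence[GroupComparison]) -> pd.DataFrame:
    """Tabulate comparisons in the CSV column order of the pipeline output."""
    return pd.DataFrame([{
        "metric": c.metric_name, "group_a": c.group_a, "group_b": c.group_b,
        "n_a": c.n_a, "n_b": c.n_b, "mean_a": c.mean_a, "mean_b": c.mean_b,
        "t": c.t_stat, "df": c.df, "p": c.p_two_tailed, "p_holm": c.p_holm,
        "significant": c.significant,
    } for c in comparisons])


@dataclass
class ConcordanceResult:
    """Agreement between ordinal visual grades and spectral OD values."""

    rs: float
    p_rs: float
    ols_slope: float
    p_slope: float
    n: int


def grade_od_concordance(grades: Sequence[int], ods: Sequence[float]) -> ConcordanceResult:
    """Spearman rank correlation and OLS slope of OD on grade code (1-4).

    Constant grades leave the rank correlation undefined (NaN, flagged
    missing); the regression slope is still computed when possible.
    """
    g = np.asarray(grades, dtype=float)
    o = np.asarray(ods, dtype=float)
    if g.size != o.size:
        raise ParameterError("grades and ODs must have equal length")
    if g.size < 3:
        raise InsufficientDataError("concordance needs >= 3 paired observations")
    if np.any((g < 1) | (g > 4)):
        raise ParameterError("grades must be coded 1-4")

    if np.ptp(g) == 0:
        rs, p_rs = float("nan"), float("nan")
        slope, p_slope = float("nan"), float("nan")
    else:
        rho = sps.spearmanr(g, o)
        rs, p_rs = float(rho.statistic), float(rho.pvalue)
        reg = sps.linregress(g, o)
        slope, p_slope = float(reg.slope), float(reg.pvalue)
    return ConcordanceResult(rs=rs, p_rs=p_rs, ols_slope=slope, p_slope=p_slope, n=int(g.size))
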