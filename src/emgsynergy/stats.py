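"""Between-group scalar comparisons: Mann-Whitney U and Cohen's d.

Outcomes (synergy counts, sparseness, demographics) are compared with the
two-sided Mann-Whitney U test — exact enumeration when both samples have at
most 10 observations and no ties, otherwise the normal approximation with
midrank tie correction — and effect sizes as Cohen's d with the pooled
(n-1-denominator) standard deviation, reported as a magnitude plus direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import EmptySetError, InsufficientSampleError, UndefinedEffectError

EXACT_MAX_N = 10


@dataclass
class MannWhitneyResult:
    u_statistic: float
    p_value: float
    method: str  # "exact" or "asymptotic"


@dataclass
class ComparisonResult:
    variable: str
    median_A: float
    range_A: tuple[float, float]
    median_B: float
    range_B: tuple[float, float]
    u_statistic: float
    p_value: float
    effect_size_d: float | None
    direction: str   # "A>B", "B>A" or "="
    method: str


def mann_whitney(sample_A, sample_B) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U (U of sample A, midrank ties)."""
    a = np.asarray(sample_A, dtype=float)
    b = np.asarray(sample_B, dtype=float)
    if a.size == 0 or b.size == 0:
        raise EmptySetError("both samples must be non-empty")
    combined = np.concatenate([a, b])
    no_ties = np.unique(combined).size == combined.size
    if no_ties and a.size <= EXACT_MAX_N and b.size <= EXACT_MAX_N:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return MannWhitneyResult(u_statistic=float(res.statistic),
                             p_value=float(res.pvalue), method=method)


def cohens_d(sample_A, sample_B) -> float:
    """|mean_A - mean_B| / pooled SD (pooled with n-1 denominators)."""
    a = np.asarray(sample_A, dtype=float)
    b = np.asarray(sample_B, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientSampleError("each sample needs >= 2 values")
    na, nb = a.size, b.size
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if pooled_var == 0:
        raise UndefinedEffectError("pooled standard deviation is zero")
    return float(abs(a.mean() - b.mean()) / np.sqrt(pooled_var))


def summarize(variable: str, sample_A, sample_B) -> ComparisonResult:
    """Assemble the median (min-max), U, p and effect size for one variable."""
    a = np.asarray(sample_A, dtype=float)
    b = np.asarray(sample_B, dtype=float)
    mw = mann_whitney(a, b)
    try:
        d = cohens_d(a, b)
    except (UndefinedEffectError, InsufficientSampleError):
        d = None
    if a.mean() > b.mean():
        direction = "A>B"
    elif b.mean() > a.mean():
        direction = "B>A"
    else:
        direction = "="
    return ComparisonResult(
        variable=variable,
        median_A=float(np.median(a)), range_A=(float(a.min()), float(a.max())),
        median_B=float(np.median(b)), range_B=(float(b.min()), float(b.max())),
        u_statistic=mw.u_statistic, p_value=mw.p_value,
        effect_size_d=d, direction=direction, method=mw.method,
    )


def compare_table(df: pd.DataFrame) -> pd.DataFrame:
    """Tidy (subject, group, variable, value) table -> one comparison per
    variable, mirroring a median (min-max) / p / ES summary table."""
    groups = sorted(df["group"].unique())
    if len(groups) != 2:
        raise InsufficientSampleError(
            f"exactly two groups required, found {groups}")
    ga, gb = groups
    rows = []
    for var, sub in df.groupby("variable", sort=False):
        res = summarize(var,
                        sub.loc[sub["group"] == ga, "value"].to_numpy(),
                        sub.loc[sub["group"] == gb, "value"].to_numpy())
        rows.append({
            "variable": var,
            f"{ga}_median": res.median_A,
            f"{ga}_range": f"{res.range_A[0]:g}-{res.range_A[1]:g}",
            f"{gb}_median": res.median_B,
            f"{gb}_range": f"{res.range_B[0]:g}-{res.range_B[1]:g}",
            "U": res.u_statistic,
            "p": res.p_value,
            "ES": res.effect_size_d,
            "direction": res.direction,
            "method": res.method,
        })
    return pd.DataFrame(rows)
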