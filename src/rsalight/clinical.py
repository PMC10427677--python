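"""Demographic/clinical comparisons and brain-behaviour ROI correlations.

Covers two-sample t tests computed from printed summary statistics (Welch
and pooled variants — summary tables in the field mix both), the unpaired
Wilcoxon rank-sum test, square-root transformation of ROI similarity scores,
per-group Pearson correlations with a clinical covariate, and the Fisher
r-to-z comparison of two independent correlations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class SummaryStats:
    group: str
    mean: float
    sd: float
    n: int
    median: float | None = None
    iqr: float | None = None

    def __post_init__(self):
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        if self.n < 2:
            raise ValueError("n must be >= 2")


@dataclass(frozen=True)
class TestResult:
    statistic_name: str  # t_welch | t_pooled | wilcoxon_w
    statistic: float
    p_value: float
    df: float | None = None
    tails: int = 2


def two_sample_t_from_summary(
    a: SummaryStats, b: SummaryStats, variant: str = "welch", tails: int = 2
) -> TestResult:
    """Two-sample t from (mean, sd, n) summaries.

    Welch uses the Welch-Satterthwaite df; pooled is the classical Student
    statistic with n_a + n_b - 2 df.
    """
    if variant not in ("welch", "pooled"):
        raise ValueError("variant must be 'welch' or 'pooled'")
    diff = a.mean - b.mean
    if a.sd == 0 and b.sd == 0:
        if diff == 0:
            raise ZeroDivisionError("t undefined: zero variance and equal means")
        return TestResult(f"t_{variant}", math.inf * np.sign(diff), 0.0,
                          df=a.n + b.n - 2, tails=tails)
    if variant == "welch":
        va, vb = a.sd**2 / a.n, b.sd**2 / b.n
        se = math.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    else:
        sp2 = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / (a.n + b.n - 2)
        se = math.sqrt(sp2 * (1 / a.n + 1 / b.n))
        df = a.n + b.n - 2
    t = diff / se
    p = stats.t.sf(abs(t), df) * tails if tails == 2 else stats.t.sf(t, df)
    return TestResult(f"t_{variant}", t, float(p), df=float(df), tails=tails)


def wilcoxon_rank_sum(x, y, alternative: str = "two-sided") -> TestResult:
    """Unpaired Wilcoxon rank-sum test.

    The statistic is reported with the R ``wilcox.test`` convention
    (W = rank sum of ``x`` minus n_x(n_x+1)/2, i.e. the Mann-Whitney U of the
    first sample).  Exact p for small untied samples, normal approximation
    with tie correction otherwise (scipy's policy).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.mannwhitneyu(x, y, alternative=alternative, method="auto")
    return TestResult("wilcoxon_w", float(res.statistic), float(res.pvalue),
                      df=None, tails=2 if alternative == "two-sided" else 1)


def sqrt_transform(values, policy: str = "strict"):
    """Elementwise square root of similarity scores.

    ``strict`` (default) raises on negative input, listing offending indices;
    ``signed`` applies sign(x) * sqrt(|x|).
    """
    if policy not in ("strict", "signed"):
        raise ValueError("policy must be 'strict' or 'signed'")
    arr = np.asarray(values, dtype=float)
    if policy == "strict":
        bad = np.where(arr < 0)[0]
        if bad.size:
            idx = (
                list(values.index[bad]) if isinstance(values, pd.Series) else bad.tolist()
            )
            raise ValueError(
                f"negative values under strict sqrt policy at {idx}; "
                "use policy='signed' for a signed root"
            )
        out = np.sqrt(arr)
    else:
        out = np.sign(arr) * np.sqrt(np.abs(arr))
    if isinstance(values, pd.Series):
        return pd.Series(out, index=values.index)
    return out


@dataclass(frozen=True)
class ExclusionRule:
    """Drop subjects whose post-scan rating is zero before correlating.

    ``rating_field`` names the participants column carrying the rating
    that is screened for zeros; None disables the rule.
    """

    rating_field: str | None = None

    def apply(self, records: pd.DataFrame) -> pd.Series:
        keep = pd.Series(True, index=records.index)
        if self.rating_field is not None:
            keep &= records[self.rating_field].fillna(0) != 0
        return keep


def correlate_roi_clinical(
    scores: Mapping[str, float] | pd.Series,
    records: pd.DataFrame,
    covariate_field: str = "ham_a",
    exclusion_rule: ExclusionRule | None = None,
    transform_policy: str = "strict",
) -> pd.DataFrame:
    """Pearson r (two-tailed p) of sqrt-transformed ROI scores vs a covariate.

    Returns one row for the whole cohort plus one per group; subjects with a
    missing covariate are dropped, and the zero-rating exclusion applied when
    a rule is given.
    """
    scores = pd.Series(scores)
    df = records.set_index("subject_id").loc[scores.index].copy()
    df["score"] = sqrt_transform(scores, policy=transform_policy)
    keep = df[covariate_field].notna() & df["score"].notna()
    if exclusion_rule is not None:
        keep &= exclusion_rule.apply(df)
    df = df[keep]
    rows = []
    for label, sub in [("all", df), *list(df.groupby("group"))]:
        if len(sub) < 3:
            raise ValueError(
                f"fewer than 3 complete pairs for cohort {label!r} after exclusions"
            )
        r, p = stats.pearsonr(sub["score"], sub[covariate_field].astype(float))
        rows.append({"cohort": str(label), "r": float(r), "p": float(p), "n": len(sub)})
    return pd.DataFrame(rows)


def fisher_z_compare(
    r1: float, n1: int, r2: float, n2: int, tails: int = 1
) -> tuple[float, float]:
    """Fisher r-to-z comparison of two independent correlations.

    z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3)); the default is a
    one-sided upper-tail p (r1 > r2).
    """
    for r, n in ((r1, n1), (r2, n2)):
        if abs(r) >= 1:
            raise ValueError("|r| must be < 1")
        if n <= 3:
            raise ValueError("each sample needs n > 3")
    z = (math.atanh(r1) - math.atanh(r2)) / math.sqrt(1 / (n1 - 3) + 1 / (n2 - 3))
    if tails == 1:
        p = stats.norm.sf(z)
    elif tails == 2:
        p = 2 * stats.norm.sf(abs(z))
    else:
        raise ValueError("tails must be 1 or 2")
    return float(z), float(p)


def summary_from_sample(group: str, values: Iterable[float]) -> SummaryStats:
    v = np.asarray([x for x in values if np.isfinite(x)], dtype=float)
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return SummaryStats(
        group=group, mean=float(v.mean()), sd=float(v.std(ddof=1)), n=len(v),
        median=float(med), iqr=float(q3 - q1),
    )
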