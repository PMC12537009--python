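"""Gated two-sample testing and nonparametric multi-group comparisons.

The decision procedure mirrors common electrophysiology practice: both
samples are tested for normality (Jarque-Bera) and for equality of
variances (two-tailed F-test); a two-tailed Student's t-test (pooled
variance) is used only when all three gates pass at alpha, otherwise the
Mann-Whitney-Wilcoxon test.  For three or more groups, Kruskal-Wallis with
Dunn's post-hoc z tests and a multiplicity adjustment is used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SampleSummary",
    "GroupComparison",
    "summarize",
    "select_two_sample_test",
    "run_two_sample",
    "kruskal_dunn",
    "format_summary",
]


@dataclass(frozen=True)
class SampleSummary:
    mean: float
    sem: float  # NaN for n == 1
    sd: float  # NaN for n == 1
    n: int


@dataclass
class GroupComparison:
    """Result of the gated two-sample comparison."""

    test_used: str  # "student_t" | "mann_whitney"
    statistic: float
    p: float
    normality_p_a: float
    normality_p_b: float
    variance_p: float
    summary_a: SampleSummary
    summary_b: SampleSummary
    alpha: float
    mw_method: str | None = None  # "exact" | "asymptotic" when Mann-Whitney ran


def summarize(x) -> SampleSummary:
    """Mean, SEM and SD (n-1 denominator) of one sample; SD/SEM are NaN for n=1."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty sample")
    n = int(x.size)
    if n == 1:
        return SampleSummary(mean=float(x[0]), sem=float("nan"), sd=float("nan"), n=1)
    sd = float(x.std(ddof=1))
    return SampleSummary(mean=float(x.mean()), sem=sd / np.sqrt(n), sd=sd, n=n)


def _f_test(x: np.ndarray, y: np.ndarray) -> float:
    """Two-tailed F-test p-value for equality of variances."""
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        return 1.0
    if vy == 0 or vx == 0:
        return 0.0
    f = vx / vy
    dist = sps.f(len(x) - 1, len(y) - 1)
    return float(min(1.0, 2.0 * min(dist.cdf(f), dist.sf(f))))


def select_two_sample_test(x, y, alpha: float = 0.05) -> dict:
    """Run the gates and decide: Student's t iff both Jarque-Bera p-values
    and the F-test p-value all exceed alpha, else Mann-Whitney."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError(f"need n >= 3 per sample, got {len(x)} and {len(y)}")
    jb_a = float(sps.jarque_bera(x).pvalue)
    jb_b = float(sps.jarque_bera(y).pvalue)
    fp = _f_test(x, y)
    use_t = jb_a > alpha and jb_b > alpha and fp > alpha
    return {
        "test": "student_t" if use_t else "mann_whitney",
        "normality_p_a": jb_a,
        "normality_p_b": jb_b,
        "variance_p": fp,
        "alpha": alpha,
    }


def run_two_sample(x, y, alpha: float = 0.05) -> GroupComparison:
    """Execute the gated two-tailed two-sample comparison.

    Student's t uses the pooled-variance form (the gate has already required
    variance equality).  Mann-Whitney is exact for small samples without
    ties, otherwise the tie-corrected normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    gate = select_two_sample_test(x, y, alpha=alpha)
    mw_method = None
    if gate["test"] == "student_t":
        res = sps.ttest_ind(x, y, equal_var=True)
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        pooled = np.concatenate([x, y])
        no_ties = len(np.unique(pooled)) == len(pooled)
        mw_method = "exact" if (no_ties and len(x) <= 25 and len(y) <= 25) else "asymptotic"
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method=mw_method)
        stat, p = float(res.statistic), float(res.pvalue)
    return GroupComparison(
        test_used=gate["test"],
        statistic=stat,
        p=p,
        normality_p_a=gate["normality_p_a"],
        normality_p_b=gate["normality_p_b"],
        variance_p=gate["variance_p"],
        summary_a=summarize(x),
        summary_b=summarize(y),
        alpha=alpha,
        mw_method=mw_method,
    )


def kruskal_dunn(
    groups: dict, *, adjust: str = "holm", alpha: float = 0.05
) -> tuple[float, float, pd.DataFrame]:
    """Kruskal-Wallis omnibus test plus Dunn's pairwise post-hoc z tests.

    ``groups`` maps labels to samples (each n >= 2); requires >= 3 groups
    (use `run_two_sample` for two).  Dunn's z statistics use the pooled
    mid-ranks with tie correction; pairwise p-values are adjusted with
    ``adjust`` ("holm", "bonferroni" or "sidak").

    Returns (H statistic, omnibus p, pairwise table).
    """
    labels = list(groups)
    if len(labels) < 3:
        raise ValueError("need >= 3 groups; use run_two_sample for two-group data")
    samples = [np.asarray(groups[g], dtype=float) for g in labels]
    if any(len(s) < 2 for s in samples):
        raise ValueError("each group needs n >= 2")
    h, p_omni = sps.kruskal(*samples)

    pooled = np.concatenate(samples)
    n_total = len(pooled)
    ranks = sps.rankdata(pooled)
    mean_ranks, sizes, start = {}, {}, 0
    for g, s in zip(labels, samples):
        mean_ranks[g] = float(ranks[start : start + len(s)].mean())
        sizes[g] = len(s)
        start += len(s)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term

    rows = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            a, b = labels[i], labels[j]
            se = np.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
            z = (mean_ranks[a] - mean_ranks[b]) / se
            rows.append({"group_a": a, "group_b": b, "z": float(z), "p_raw": float(2 * sps.norm.sf(abs(z)))})
    table = pd.DataFrame(rows)
    method = {"holm": "holm", "bonferroni": "bonferroni", "sidak": "sidak"}[adjust]
    table["p_adj"] = multipletests(table["p_raw"], alpha=alpha, method=method)[1]
    return float(h), float(p_omni), table


def format_summary(label: str, s: SampleSummary, unit: str = "") -> str:
    """Caption-style summary string: 'label: mean +/- SEM unit, SD = sd unit, n = n'."""
    u = f" {unit}" if unit else ""
    return f"{label}: {s.mean:.3g} ± {s.sem:.3g}{u}, SD = {s.sd:.3g}{u}, n = {s.n}"
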