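"""Measurement-agreement and test-retest statistics for subtest times.

Two timing methods (e.g. automatic vs ground truth) are compared with
Bland–Altman limits of agreement for repeated measures: the subject's true
time changes between repetitions (practice effect), so the variance of the
differences is decomposed into within-subject and between-subject components
by a one-way ANOVA of the differences with subject as the factor
(Bland & Altman's method for repeated measures when the measurand varies):

    sd_diff² = MS_within + max(0, (MS_between − MS_within) / m0),
    m0 = (N² − Σ nᵢ²) / ((a − 1) · N)

with a subjects, nᵢ paired differences for subject i, N = Σ nᵢ.  With one
observation per subject this reduces exactly to the classic computation.
The 95% limits of agreement are bias ± 1.96 · sd_diff.

Bias significance uses a one-sample t test on per-subject mean differences;
equality of variances uses Levene's test (mean-centred); test-retest change
uses the Wilcoxon signed-rank test with an exact null distribution (midranks,
zeros dropped) for n ≤ 25.  All p values are Bonferroni-adjusted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .recording_io import TimesTable

__all__ = ["AgreementResult", "RetestResult", "bland_altman_repeated",
           "bias_t_test", "levene_equal_variance", "wilcoxon_retest",
           "wilcoxon_exact_p"]

_Z95 = 1.96


@dataclass
class AgreementResult:
    method_pair: tuple
    field: str
    bias_s: float
    sd_diff_s: float
    loa_low_s: float
    loa_high_s: float
    n_subjects: int
    n_differences: int
    subject_means: np.ndarray = None
    t_stat: float | None = None
    p_bias: float | None = None
    p_bias_adj: float | None = None
    significant: bool | None = None
    degenerate: bool = False
    warnings: list = field(default_factory=list)

    @property
    def loa_width_s(self) -> float:
        return self.loa_high_s - self.loa_low_s


@dataclass
class RetestResult:
    median_diff_s: float
    iqr_s: float
    p_wilcoxon: float
    p_adj: float
    n: int
    method: str = "exact"


def _paired_differences(table: TimesTable, pair, field: str) -> pd.DataFrame:
    if field not in ("start", "end", "total"):
        raise ValueError("field must be one of start, end, total")
    col = f"{field}_s"
    a_name, b_name = pair
    df = table.df
    keys = ["subject_id", "repetition", "hand", "subtest"]
    a = df[df["method"] == a_name].set_index(keys)[col]
    b = df[df["method"] == b_name].set_index(keys)[col]
    for name, series in ((a_name, a), (b_name, b)):
        if series.empty:
            raise ValueError(f"no rows for method {name!r}")
    joined = pd.DataFrame({"a": a, "b": b})
    missing = joined[joined.isna().any(axis=1)]
    if len(missing):
        key = missing.index[0]
        raise ValueError(f"method/field missing for observation {key}")
    joined["d"] = joined["a"] - joined["b"]
    return joined.reset_index()


def bland_altman_repeated(table: TimesTable, pair, field: str = "total") -> AgreementResult:
    """Bland–Altman bias and 95% limits of agreement for repeated measures.

    ``pair`` is (method A, method B); differences are A − B.  Each subject
    must have at least one paired observation; the measured quantity may
    differ between repetitions.
    """
    joined = _paired_differences(table, pair, field)
    d = joined["d"].to_numpy(dtype=float)
    groups = joined.groupby("subject_id")["d"]
    means = groups.mean().to_numpy(dtype=float)
    counts = groups.count().to_numpy()
    a = len(counts)
    N = int(counts.sum())
    bias = float(d.mean())
    warnings = []

    if a == 1:
        sd = float(np.std(d, ddof=1)) if N > 1 else 0.0
        warnings.append("single subject: between-subject variance undefined, "
                        "plain SD of differences used")
    else:
        grand = bias
        ss_w = float(sum(((g - g.mean()) ** 2).sum() for _, g in groups))
        df_w = N - a
        ms_w = ss_w / df_w if df_w > 0 else 0.0
        ss_b = float((counts * (means - grand) ** 2).sum())
        ms_b = ss_b / (a - 1)
        m0 = (N ** 2 - float((counts ** 2).sum())) / ((a - 1) * N)
        between = max(0.0, (ms_b - ms_w) / m0)
        sd = float(np.sqrt(ms_w + between))

    return AgreementResult(
        method_pair=tuple(pair), field=field, bias_s=bias, sd_diff_s=sd,
        loa_low_s=bias - _Z95 * sd, loa_high_s=bias + _Z95 * sd,
        n_subjects=a, n_differences=N, subject_means=means, warnings=warnings)


def bias_t_test(result: AgreementResult, m_comparisons: int = 3) -> AgreementResult:
    """One-sample t test of the per-subject mean differences against zero,
    Bonferroni-adjusted over ``m_comparisons`` tests."""
    means = np.asarray(result.subject_means, dtype=float)
    if means.size < 2:
        raise ValueError("bias_t_test requires at least 2 subjects")
    if np.std(means, ddof=1) == 0:
        if means.mean() == 0:
            result.t_stat, result.p_bias = 0.0, 1.0
        else:
            result.t_stat, result.p_bias = np.inf, 0.0
            result.degenerate = True
            result.warnings.append("zero variance with nonzero bias: p degenerate")
    else:
        t, p = stats.ttest_1samp(means, 0.0)
        result.t_stat, result.p_bias = float(t), float(p)
    result.p_bias_adj = min(1.0, m_comparisons * result.p_bias)
    result.significant = result.p_bias_adj < 0.05
    return result


def levene_equal_variance(diff_sets: list, m_comparisons: int | None = None) -> list:
    """Classic (mean-centred) Levene test for every pair of difference sets.

    Returns one dict per pair (i, j, statistic, p, p_adj); the Bonferroni
    family defaults to the number of pairs.
    """
    sets = [np.asarray(s, dtype=float) for s in diff_sets]
    for i, s in enumerate(sets):
        if s.size < 3:
            raise ValueError(f"difference set {i} has fewer than 3 values")
    pairs = [(i, j) for i in range(len(sets)) for j in range(i + 1, len(sets))]
    m = m_comparisons if m_comparisons is not None else max(1, len(pairs))
    out = []
    for i, j in pairs:
        w, p = stats.levene(sets[i], sets[j], center="mean")
        out.append({"pair": (i, j), "statistic": float(w), "p": float(p),
                    "p_adj": min(1.0, m * float(p))})
    return out


# ---------------------------------------------------------------------------
# Wilcoxon signed rank with an exact null for small n

def _signed_rank_statistic(d: np.ndarray):
    """Positive-rank sum with zeros dropped and midranks for ties."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    if d.size == 0:
        return 0.0, np.array([])
    ranks = stats.rankdata(np.abs(d))
    return float(ranks[d > 0].sum()), ranks


def wilcoxon_exact_p(d) -> float:
    """Exact two-sided signed-rank p by dynamic programming over the null
    distribution of the positive-rank sum (each sign pattern equally likely).

    Midranks are doubled to integers so tied ranks enumerate exactly; the
    two-sided p is ``min(1, 2·min(P(W ≤ w), P(W ≥ w)))``.
    """
    w, ranks = _signed_rank_statistic(d)
    n = ranks.size
    if n == 0:
        return 1.0
    r2 = np.rint(2 * ranks).astype(int)     # doubled midranks are integers
    total = int(r2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[:total + 1 - r]
        dist = dist + shifted
    dist /= 2.0 ** n
    w2 = int(np.rint(2 * w))
    p_le = float(dist[:w2 + 1].sum())
    p_ge = float(dist[w2:].sum())
    return min(1.0, 2.0 * min(p_le, p_ge))


def wilcoxon_retest(rep1, rep2, m_comparisons: int = 3) -> RetestResult:
    """Wilcoxon signed-rank comparison of first vs second repetition.

    Exact p for up to 25 nonzero differences, normal approximation above;
    reported as the median (interquartile range) of rep1 − rep2.
    """
    rep1 = np.asarray(rep1, dtype=float)
    rep2 = np.asarray(rep2, dtype=float)
    if rep1.shape != rep2.shape or rep1.size < 5:
        raise ValueError("paired samples of equal length >= 5 required")
    d = rep1 - rep2
    median = float(np.median(d))
    q1, q3 = np.percentile(d, [25, 75])
    iqr = float(q3 - q1)
    dnz = d[d != 0]
    if dnz.size == 0:
        p, method = 1.0, "degenerate"
    elif dnz.size <= 25:
        p, method = wilcoxon_exact_p(d), "exact"
    else:
        _, p = stats.wilcoxon(dnz, method="approx")
        p, method = float(p), "normal-approx"
    return RetestResult(median_diff_s=median, iqr_s=iqr, p_wilcoxon=p,
                        p_adj=min(1.0, m_comparisons * p), n=int(rep1.size),
                        method=method)
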