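"""Group-level statistics in the reporting style of the analyses:
one-sample / paired t tests with Cohen's d, one-way repeated-measures ANOVA
with partial eta squared, and the tie-corrected Wilcoxon signed-rank z with
effect size r = z / sqrt(n).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass
class StatResult:
    test_name: str
    statistic: float
    df: tuple | int | None
    p_value: float
    effect_size: float
    effect_name: str
    n: int

    def __str__(self):
        df = self.df if self.df is not None else self.n
        return (f"{self.test_name}: stat={self.statistic:.3f}, df={df}, "
                f"p={self.p_value:.4g}, {self.effect_name}={self.effect_size:.3f}")


def one_sample_t(values, null: float = 0.0) -> StatResult:
    """t test of the mean against ``null``; Cohen's d = mean/sd."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ValueError("need at least two observations")
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance; t statistic undefined")
    res = sps.ttest_1samp(v, null)
    d = (v.mean() - null) / sd
    return StatResult("one-sample t", float(res.statistic), len(v) - 1,
                      float(res.pvalue), float(d), "cohen_d", len(v))


def paired_t(a, b) -> StatResult:
    """Paired t test; Cohen's d = mean(diff)/sd(diff)."""
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    return one_sample_t(a - b)


def rm_anova_oneway(matrix) -> StatResult:
    """One-way repeated-measures ANOVA (participants x levels), no sphericity
    correction; partial eta^2 = SS_effect / (SS_effect + SS_error)."""
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[1] < 2:
        raise ValueError("need a participants x levels matrix with >= 2 levels")
    if np.any(~np.isfinite(m)):
        raise ValueError("matrix contains missing cells")
    n, k = m.shape
    grand = m.mean()
    ss_effect = n * np.sum((m.mean(axis=0) - grand) ** 2)
    ss_subject = k * np.sum((m.mean(axis=1) - grand) ** 2)
    ss_total = np.sum((m - grand) ** 2)
    ss_error = ss_total - ss_effect - ss_subject
    df_effect = k - 1
    df_error = (k - 1) * (n - 1)
    ms_effect = ss_effect / df_effect
    ms_error = ss_error / df_error
    f = ms_effect / ms_error if ms_error > 0 else np.inf
    p = float(sps.f.sf(f, df_effect, df_error))
    eta_p2 = ss_effect / (ss_effect + ss_error) if (ss_effect + ss_error) > 0 else 0.0
    return StatResult("rm-anova", float(f), (df_effect, df_error), p,
                      float(eta_p2), "partial_eta2", n)


def wilcoxon_signed_rank(a, b) -> StatResult:
    """Wilcoxon signed-rank test via the tie-corrected normal approximation.

    Zero differences are discarded (Wilcoxon's rule); ties among the
    remaining absolute differences reduce the null variance by
    sum(t^3 - t)/48.  Effect size r = |z| / sqrt(n) with n the number of
    retained pairs.
    """
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    d = a - b
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("all differences are zero; test undefined")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, counts = np.unique(np.abs(d), return_counts=True)
    var -= np.sum(counts ** 3 - counts) / 48.0
    if var <= 0:
        raise ValueError("null variance zero (all differences tied)")
    z = (w_plus - mu) / np.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return StatResult("wilcoxon signed-rank", float(z), None, float(p),
                      float(abs(z) / np.sqrt(n)), "r", n)
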