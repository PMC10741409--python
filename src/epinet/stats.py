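"""Normality-gated paired tests, Bonferroni and Benjamini-Hochberg utilities.

Paired graph-metric comparisons follow the clinical-statistics convention:
Shapiro-Wilk on the paired differences decides between the paired t-test
(normal) and the Wilcoxon signed-rank test (otherwise).  Effect sizes are
Cohen's d_z for the t branch and r = Z / sqrt(n) for the Wilcoxon branch,
signed by the direction of the mean difference (positive = pre > rest).
Wilcoxon p-values are exact for up to 25 nonzero differences and use the
normal approximation with continuity correction above that; zero differences
are dropped.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class PairedTestResult:
    metric: str
    band: str | None
    n: int
    test: str                  # "wilcoxon" | "paired-t" | "degenerate"
    statistic: float
    p_raw: float
    p_corrected: float | None
    effect_r: float
    median_pre: float
    median_rest: float
    degenerate: bool = False


def _wilcoxon_z(d: np.ndarray) -> float:
    """Signed-rank Z (no continuity correction), signed by the rank sums."""
    d = d[d != 0]
    n = d.size
    ranks = stats.rankdata(np.abs(d))
    w_plus = ranks[d > 0].sum()
    mu = n * (n + 1) / 4.0
    sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0)
    return float((w_plus - mu) / sigma) if sigma > 0 else 0.0


def paired_metric_test(values_pre, values_rest, alpha_normality: float = 0.05,
                       force: str = "auto", metric: str = "", band: str | None = None,
                       ) -> PairedTestResult:
    """Paired comparison of one metric between conditions.

    ``force`` may pin the branch to ``"wilcoxon"`` or ``"t"`` (used in tests
    and when the normality gate is decided elsewhere); ``"auto"`` applies the
    Shapiro-Wilk gate at ``alpha_normality``.
    """
    pre = np.asarray(values_pre, dtype=float)
    rest = np.asarray(values_rest, dtype=float)
    if pre.shape != rest.shape or pre.ndim != 1:
        raise ValueError("values_pre and values_rest must be equal-length 1-D vectors")
    n = pre.size
    if n < 4:
        raise ValueError("need at least 4 pairs")
    d = pre - rest
    med_pre, med_rest = float(np.median(pre)), float(np.median(rest))

    if np.all(d == 0):
        return PairedTestResult(metric=metric, band=band, n=n, test="degenerate",
                                statistic=0.0, p_raw=1.0, p_corrected=None,
                                effect_r=0.0, median_pre=med_pre,
                                median_rest=med_rest, degenerate=True)

    if force == "auto":
        if np.ptp(d) == 0:
            use_t = False          # constant nonzero differences: not normal
        else:
            use_t = bool(stats.shapiro(d).pvalue >= alpha_normality)
    elif force in ("t", "paired-t"):
        use_t = True
    elif force == "wilcoxon":
        use_t = False
    else:
        raise ValueError(f"force must be 'auto', 't' or 'wilcoxon', got {force!r}")

    if use_t:
        res = stats.ttest_rel(pre, rest)
        effect = float(d.mean() / d.std(ddof=1))          # Cohen's d_z
        return PairedTestResult(metric=metric, band=band, n=n, test="paired-t",
                                statistic=float(res.statistic), p_raw=float(res.pvalue),
                                p_corrected=None, effect_r=effect,
                                median_pre=med_pre, median_rest=med_rest)

    nz = d[d != 0]
    if np.ptp(nz) == 0:
        # all nonzero differences identical: exact two-sided sign-pattern p
        p = min(1.0, 2.0 / 2 ** nz.size)
        w = float(np.abs(nz).sum() if nz[0] > 0 else 0.0)
    else:
        method = "exact" if nz.size <= 25 else "approx"
        res = stats.wilcoxon(nz, zero_method="wilcox", method=method,
                             correction=(method == "approx"))
        p, w = float(res.pvalue), float(res.statistic)
    z = _wilcoxon_z(d)
    effect = float(np.sign(d.mean() or z) * abs(z) / np.sqrt(n))
    return PairedTestResult(metric=metric, band=band, n=n, test="wilcoxon",
                            statistic=w, p_raw=p, p_corrected=None, effect_r=effect,
                            median_pre=med_pre, median_rest=med_rest)


def bonferroni(results: list[PairedTestResult], m: int | None = None,
               ) -> list[PairedTestResult]:
    """Bonferroni-correct a family of results (default m = family size)."""
    if not results:
        raise ValueError("need at least one result")
    m = len(results) if m is None else m
    return [replace(r, p_corrected=min(1.0, r.p_raw * m)) for r in results]


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone enforced)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p, dtype=float)
    if p.size < 1:
        raise ValueError("need at least one p-value")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
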