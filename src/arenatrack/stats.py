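"""Agreement and inference statistics used to validate trackers and raters.

Implements the single-rater intraclass correlation coefficients from the
two-way ANOVA decomposition — ICC(2,1), two-way random effects, absolute
agreement, and ICC(3,1), two-way mixed effects, consistency — plus thin,
validated wrappers for Pearson correlation, paired and one-sample t-tests,
Benjamini–Hochberg FDR adjustment, and Kruskal–Wallis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


class StatsError(ValueError):
    pass


@dataclass
class PairedRatings:
    """n subjects rated by k methods; complete n x k matrix."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise StatsError("ratings must be a 2-D (subjects x raters) matrix")
        n, k = self.values.shape
        if n < 2 or k < 2:
            raise StatsError("need at least 2 subjects and 2 raters")
        if not np.isfinite(self.values).all():
            raise StatsError("ratings must be finite (no missing values)")


def pearson_r(x, y) -> tuple[float, float]:
    """Sample Pearson correlation with a two-sided p (t distribution, n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise StatsError("x and y must be 1-D of equal length")
    if len(x) < 3:
        raise StatsError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise StatsError("zero variance input")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def _anova_mean_squares(values: np.ndarray) -> tuple[float, float, float]:
    """Two-way (subjects x raters, one observation per cell) mean squares:
    rows (MSR), columns (MSC), residual (MSE)."""
    n, k = values.shape
    grand = values.mean()
    row_means = values.mean(axis=1)
    col_means = values.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((values - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return msr, msc, mse


def icc(ratings: PairedRatings, model: str = "icc2") -> tuple[float, float]:
    """Single-rater ICC from the two-way ANOVA decomposition.

    ``icc2``: absolute agreement, two-way random effects —
        (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n).
    ``icc3``: consistency, two-way mixed effects —
        (MSR - MSE) / (MSR + (k-1) MSE).
    p-value from F = MSR/MSE with (n-1, (n-1)(k-1)) df.
    """
    values = ratings.values
    n, k = values.shape
    if np.ptp(values) == 0:
        raise StatsError("degenerate ratings: all values equal")
    msr, msc, mse = _anova_mean_squares(values)
    if model == "icc2":
        val = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    elif model == "icc3":
        val = (msr - mse) / (msr + (k - 1) * mse)
    else:
        raise StatsError(f"unknown ICC model {model!r}")
    if mse == 0:
        p = 0.0
    else:
        f = msr / mse
        p = float(sps.f.sf(f, n - 1, (n - 1) * (k - 1)))
    return float(val), p


def _t_from_diffs(d: np.ndarray) -> tuple[float, float]:
    n = len(d)
    sd = d.std(ddof=1)
    if sd == 0:
        if np.allclose(d, 0):
            return 0.0, 1.0
        # nonzero constant difference: infinitely strong evidence
        return float(np.sign(d.mean()) * np.inf), float("nan")
    t = d.mean() / (sd / np.sqrt(n))
    p = 2 * sps.t.sf(abs(t), n - 1)
    return float(t), float(p)


def paired_t(x, y) -> tuple[float, float]:
    """Two-sided paired t-test; zero-variance differences are degenerate
    (t=0, p=1 when all differences are zero, else t=+/-inf, p=nan)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or len(x) < 2:
        raise StatsError("paired samples must have equal length >= 2")
    return _t_from_diffs(x - y)


def one_sample_t(x, mu0: float) -> tuple[float, float]:
    """Two-sided one-sample t-test of mean(x) against mu0."""
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        raise StatsError("need at least 2 observations")
    return _t_from_diffs(x - mu0)


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, capped at 1."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals
    return multipletests(pvals, method="fdr_bh")[1]


def kruskal_wallis(groups) -> tuple[float, float]:
    """Kruskal–Wallis H and p; identical-valued groups give (0, 1)."""
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2 or any(len(a) < 2 for a in arrs):
        raise StatsError("need >= 2 groups with >= 2 observations each")
    pooled = np.concatenate(arrs)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    h, p = sps.kruskal(*arrs)
    return float(h), float(p)
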