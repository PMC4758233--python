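"""Nonparametric class-comparison statistics and PCA.

Mann–Whitney U (exact for small tie-free samples, else the normal
approximation with tie correction and continuity correction), Spearman
rank correlation, coefficient of variation, the pooled two-proportion z
test, principal component analysis on the correlation matrix with a
|loading| retention threshold, and frequency histograms. All tests are
two-sided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.proportion import proportions_ztest

EXACT_MWU_MAX_POOLED = 12


@dataclass
class TestResult:
    statistic: float
    p_value: float
    n1: int
    n2: int
    method: str
    sidedness: str = "two-sided"
    flags: list[str] = field(default_factory=list)


@dataclass
class PCAResult:
    component_variance_pct: np.ndarray
    loadings: pd.DataFrame          # features x components
    retained: list[list[str]]       # per-component features with |loading| > threshold
    n_complete_cases: int
    threshold: float


def _clean(x) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    return arr[~np.isnan(arr)]


def mann_whitney_u(x, y) -> TestResult:
    """Two-sided Mann–Whitney U test of two independent samples.

    U is the midrank-based statistic of the first sample. The p-value
    is exact (full enumeration) when the pooled size is <= 12 with no
    ties, otherwise from the tie-corrected normal approximation with
    continuity correction. A pooled sample with zero variance yields
    p = 1 with a "zero_variance" flag.
    """
    x, y = _clean(x), _clean(y)
    n1, n2 = len(x), len(y)
    if n1 < 1 or n2 < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return TestResult(
            statistic=n1 * n2 / 2.0,
            p_value=1.0,
            n1=n1,
            n2=n2,
            method="mwu-degenerate",
            flags=["zero_variance"],
        )
    has_ties = len(np.unique(pooled)) < n1 + n2
    if n1 + n2 <= EXACT_MWU_MAX_POOLED and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        n1=n1,
        n2=n2,
        method=f"mwu-{method}",
    )


def spearman_rho(x, y) -> TestResult:
    """Spearman rank correlation of paired vectors (pairwise deletion).

    rho is the Pearson correlation of midranks; the p-value comes from
    the t approximation with n - 2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("paired vectors must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise ValueError("Spearman correlation requires >= 3 complete pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return TestResult(
            statistic=float("nan"), p_value=float("nan"), n1=n, n2=n,
            method="spearman", flags=["zero_rank_variance"],
        )
    rho, p = sps.spearmanr(x, y)
    return TestResult(statistic=float(rho), p_value=float(p), n1=n, n2=n,
                      method="spearman")


def coefficient_of_variation(x) -> float:
    """Sample SD (n-1 denominator) divided by the mean; mean 0 undefined."""
    x = _clean(x)
    mean = x.mean()
    if mean == 0:
        raise ValueError("coefficient of variation undefined for zero mean")
    sd = x.std(ddof=1) if len(x) > 1 else 0.0
    return float(sd / mean)


def two_proportion_z(k1: int, n1: int, k2: int, n2: int) -> TestResult:
    """Pooled two-proportion z test, two-sided.

    Negative z when the first group's proportion is smaller. Undefined
    (raises) when the pooled proportion is 0 or 1.
    """
    for k, n in ((k1, n1), (k2, n2)):
        if not (0 <= k <= n) or n < 1:
            raise ValueError("need 0 <= k <= n and n >= 1")
    pooled = (k1 + k2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        raise ValueError("two-proportion z undefined: pooled proportion is 0 or 1")
    z, p = proportions_ztest([k1, k2], [n1, n2], alternative="two-sided")
    return TestResult(statistic=float(z), p_value=float(p), n1=n1, n2=n2,
                      method="two-proportion-z")


def pca(features: pd.DataFrame, loading_threshold: float = 0.5) -> PCAResult:
    """PCA of the correlation matrix with a |loading| retention rule.

    Complete-case rows only; variables are standardised, the correlation
    matrix is eigendecomposed, loadings are eigenvector * sqrt(eigenvalue)
    (the correlation of each variable with the component), and each
    component's sign is fixed so its largest-magnitude loading is
    positive. Per component, variables with |loading| > threshold form
    the retained set.
    """
    if not isinstance(features, pd.DataFrame):
        features = pd.DataFrame(np.asarray(features, dtype=float))
    data = features.astype(float).dropna(axis=0, how="any")
    n, p = data.shape
    if p < 2:
        raise ValueError("PCA requires >= 2 variables")
    if n < 2:
        raise ValueError("PCA requires >= 2 complete-case rows")
    stds = data.std(ddof=1)
    constant = stds[stds == 0].index.tolist()
    if constant:
        raise ValueError(f"constant variable(s) in PCA input: {constant}")
    if n < p:
        warnings.warn(f"fewer complete cases ({n}) than variables ({p})")
    corr = np.corrcoef(data.to_numpy(), rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    variance_pct = 100.0 * eigval / eigval.sum()
    loadings = eigvec * np.sqrt(eigval)
    for j in range(p):
        i_max = np.argmax(np.abs(loadings[:, j]))
        if loadings[i_max, j] < 0:
            loadings[:, j] = -loadings[:, j]
    loading_df = pd.DataFrame(
        loadings,
        index=data.columns,
        columns=[f"PC{j + 1}" for j in range(p)],
    )
    retained = [
        loading_df.index[np.abs(loading_df[f"PC{j + 1}"]) > loading_threshold].tolist()
        for j in range(p)
    ]
    return PCAResult(
        component_variance_pct=variance_pct,
        loadings=loading_df,
        retained=retained,
        n_complete_cases=n,
        threshold=loading_threshold,
    )


def histogram(values, bin_width: float) -> pd.DataFrame:
    """Frequency-percent histogram on left-closed bins anchored at 0.

    Returns columns (bin_center, frequency_pct); NaNs are dropped and
    percentages are of the non-missing values.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    vals = _clean(values)
    if len(vals) == 0:
        return pd.DataFrame(columns=["bin_center", "frequency_pct"])
    idx = np.floor(vals / bin_width).astype(int)
    lo, hi = idx.min(), idx.max()
    counts = np.bincount(idx - lo, minlength=hi - lo + 1)
    centers = (np.arange(lo, hi + 1) + 0.5) * bin_width
    return pd.DataFrame(
        {"bin_center": centers, "frequency_pct": 100.0 * counts / len(vals)}
    )


def histogram_mode_bin(hist: pd.DataFrame) -> tuple[float, float]:
    """(bin_center, frequency_pct) of the most populated bin."""
    if hist.empty:
        raise ValueError("empty histogram")
    row = hist.loc[hist["frequency_pct"].idxmax()]
    return float(row["bin_center"]), float(row["frequency_pct"])
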