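"""Residual summaries and the variance F-test comparing loading precision.

The pooled residuals R = C − BA_L from each chemometric method form one
sample per method. Accuracy is judged by whether the 95% confidence interval
on the mean of R covers zero (t interval, n − 1 df); precision by a one-
tailed F-test of the variance ratio under

    H0: σ²(R_PLS) = σ²(R_PCR)      Ha: σ²(R_PLS) > σ²(R_PCR)

The F statistic is oriented as var(R_PCR) / var(R_PLS), with the LOWER tail
probability P(F ≤ f) reported: small values support the alternative that
PLS loadings scatter more widely than PCR loadings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

__all__ = [
    "ResidualSummary",
    "FTestResult",
    "summarize_residuals",
    "summary_from_moments",
    "ci95_halfwidth",
    "f_test_variances",
    "f_test_from_variances",
    "mean_ci_covers_zero",
    "residual_histogram",
    "skewness",
]


@dataclass(frozen=True)
class ResidualSummary:
    method: str | None
    n: int
    mean_r: float  # cm⁻¹
    variance_r: float  # cm⁻²; n−1 denominator
    sd_r: float  # cm⁻¹
    ci95_halfwidth: float  # cm⁻¹
    df: int  # n − 1


@dataclass(frozen=True)
class FTestResult:
    f: float  # var(R_PCR) / var(R_PLS)
    df_num: int
    df_den: int
    p_one_tail: float  # P(F ≤ f), the lower tail
    significant_at_95: bool


def ci95_halfwidth(sd: float, n: int) -> float:
    """Half-width of the normal-theory 95% interval on a mean:
    t(0.975, n−1) · sd / √n."""
    if n < 2:
        raise ValueError("need n >= 2")
    return float(sstats.t.ppf(0.975, n - 1) * sd / math.sqrt(n))


def summary_from_moments(
    mean: float, variance: float, n: int, method: str | None = None
) -> ResidualSummary:
    """Summary from already-computed sample moments (e.g. a published table)."""
    if n < 2:
        raise ValueError("need n >= 2")
    if variance < 0:
        raise ValueError("variance must be >= 0")
    sd = math.sqrt(variance)
    return ResidualSummary(
        method=method,
        n=n,
        mean_r=float(mean),
        variance_r=float(variance),
        sd_r=sd,
        ci95_halfwidth=ci95_halfwidth(sd, n),
        df=n - 1,
    )


def summarize_residuals(
    r_values: "list[float] | np.ndarray", method: str | None = None
) -> ResidualSummary:
    """Sample mean, variance (n−1), sd and 95% t-interval half-width."""
    r = np.asarray(r_values, dtype=float).ravel()
    if r.size < 2:
        raise ValueError("need at least two residuals")
    return summary_from_moments(float(r.mean()), float(r.var(ddof=1)), r.size, method)


def f_test_from_variances(
    var_pcr: float, var_pls: float, n_pcr: int, n_pls: int, alpha: float = 0.05
) -> FTestResult:
    """One-tailed variance-ratio test from sample variances and sizes.

    F = var(R_PCR)/var(R_PLS); significance is the lower-tail probability
    P(F(n_pcr−1, n_pls−1) ≤ F) falling below alpha.
    """
    if min(n_pcr, n_pls) < 2:
        raise ValueError("each group needs n >= 2")
    if var_pls <= 0:
        raise ValueError("degenerate test: PLS residual variance is zero")
    if var_pcr < 0:
        raise ValueError("variance must be >= 0")
    f = var_pcr / var_pls
    p = float(sstats.f.cdf(f, n_pcr - 1, n_pls - 1))
    return FTestResult(
        f=float(f),
        df_num=n_pcr - 1,
        df_den=n_pls - 1,
        p_one_tail=p,
        significant_at_95=p < alpha,
    )


def f_test_variances(
    r_pcr: "list[float] | np.ndarray",
    r_pls: "list[float] | np.ndarray",
    alpha: float = 0.05,
) -> FTestResult:
    """One-tailed F-test of var(R_PCR)/var(R_PLS) from the residual samples."""
    a = np.asarray(r_pcr, dtype=float).ravel()
    b = np.asarray(r_pls, dtype=float).ravel()
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    return f_test_from_variances(
        float(a.var(ddof=1)), float(b.var(ddof=1)), a.size, b.size, alpha
    )


def mean_ci_covers_zero(summary: ResidualSummary) -> bool:
    """True when the 95% interval on mean R overlaps zero — the accuracy
    criterion for wavenumber assignment."""
    return abs(summary.mean_r) <= summary.ci95_halfwidth


def residual_histogram(
    r_values: "list[float] | np.ndarray", bin_width_cm1: float
) -> tuple[np.ndarray, np.ndarray]:
    """Fixed-width histogram of the residuals; returns (bin_edges, counts).

    Edges align to multiples of the bin width and cover the data range;
    counts always sum to n.
    """
    if bin_width_cm1 <= 0:
        raise ValueError("bin width must be positive")
    r = np.asarray(r_values, dtype=float).ravel()
    if r.size == 0:
        raise ValueError("no residuals to bin")
    lo = math.floor(r.min() / bin_width_cm1) * bin_width_cm1
    nbins = max(1, math.ceil((r.max() - lo) / bin_width_cm1 + 1e-12))
    edges = lo + bin_width_cm1 * np.arange(nbins + 1)
    counts, _ = np.histogram(r, bins=edges)
    return edges, counts


def skewness(r_values: "list[float] | np.ndarray") -> float:
    """Sample skewness; |skew| > 1 flags residual pools whose normal-theory
    intervals should be read with caution."""
    return float(sstats.skew(np.asarray(r_values, dtype=float).ravel()))
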