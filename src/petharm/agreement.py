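"""Agreement statistics for paired activity-concentration measurements.

Summarizes percentage differences (mean/median/SD/range), computes Lin's
concordance correlation coefficient (CCC) with a 95% confidence interval and
McBride strength class, compares subgroups with the Mann-Whitney U test, and
applies the acceptance rule: agreement is acceptable when the mean percentage
difference is within +-10% (accuracy) and its SD within 25% (precision).

Lin's CCC uses the original moment definition with n-denominator moments,

    rho_c = 2 s_xy / (s_x^2 + s_y^2 + (xbar - ybar)^2),

which penalizes both scatter (Pearson correlation) and departure from the
identity line (bias-correction factor), so |rho_c| <= |r| always.  The CI is
built on the Fisher z transform of rho_c with Lin's asymptotic variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "DescriptiveStats",
    "ConcordanceResult",
    "AcceptanceVerdict",
    "describe",
    "lins_ccc",
    "mann_whitney",
    "acceptance_check",
    "mcbride_class",
]


@dataclass(frozen=True)
class DescriptiveStats:
    """mean (median) +- SD (min to max) of a sample; SD uses the n-1 denominator."""

    n: int
    mean: float
    median: float
    sd: float
    min: float
    max: float


@dataclass(frozen=True)
class ConcordanceResult:
    rho_c: float
    ci_low: float
    ci_high: float
    n: int
    mcbride_class: str


@dataclass(frozen=True)
class AcceptanceVerdict:
    mean_ok: bool
    sd_ok: bool

    @property
    def accepted(self) -> bool:
        return self.mean_ok and self.sd_ok


def describe(values) -> DescriptiveStats:
    """Sample descriptive statistics; requires n >= 2 (the SD is undefined
    below that).  The median of an even-length sample is the midpoint of the
    two central order statistics."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        x = x.ravel()
    if x.size < 2:
        raise ValueError("need at least 2 values for descriptive statistics")
    return DescriptiveStats(
        n=int(x.size),
        mean=float(x.mean()),
        median=float(np.median(x)),
        sd=float(x.std(ddof=1)),
        min=float(x.min()),
        max=float(x.max()),
    )


def mcbride_class(rho_c: float) -> str:
    """Strength-of-agreement band for a CCC value: > 0.99 almost perfect,
    0.95-0.99 substantial, 0.90-0.95 moderate, < 0.90 poor."""
    if rho_c > 0.99:
        return "almost perfect"
    if rho_c >= 0.95:
        return "substantial"
    if rho_c >= 0.90:
        return "moderate"
    return "poor"


def lins_ccc(x, y, alpha: float = 0.05) -> ConcordanceResult:
    """Lin's concordance correlation coefficient with an asymptotic CI.

    Moments use the n denominator (Lin 1989).  The confidence interval is the
    Fisher-z interval: Z = atanh(rho_c), Z +- z_{1-alpha/2} * sqrt(var(Z))
    with Lin's asymptotic variance of the transformed estimate, then
    back-transformed with tanh.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D arrays of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 pairs for a concordance CI")
    sx2 = x.var(ddof=0)
    sy2 = y.var(ddof=0)
    if sx2 == 0 or sy2 == 0:
        raise ValueError("zero variance in x or y; concordance undefined")
    sxy = np.mean((x - x.mean()) * (y - y.mean()))
    dmean = x.mean() - y.mean()
    rho_c = 2.0 * sxy / (sx2 + sy2 + dmean**2)

    r = sxy / np.sqrt(sx2 * sy2)  # Pearson on n-denominator moments
    u = dmean / (sx2 * sy2) ** 0.25  # location shift relative to scale

    if abs(rho_c) >= 1.0 or abs(r) >= 1.0:
        # perfect concordance: degenerate CI at the point estimate
        return ConcordanceResult(float(rho_c), float(rho_c), float(rho_c), n, mcbride_class(rho_c))

    # Lin's asymptotic variance of atanh(rho_c)
    var_z = (
        (1 - r**2) * rho_c**2 / ((1 - rho_c**2) * r**2)
        + 2 * rho_c**3 * (1 - rho_c) * u**2 / (r * (1 - rho_c**2) ** 2)
        - rho_c**4 * u**4 / (2 * r**2 * (1 - rho_c**2) ** 2)
    ) / (n - 2)
    zcrit = stats.norm.ppf(1 - alpha / 2.0)
    z = np.arctanh(rho_c)
    half = zcrit * np.sqrt(max(var_z, 0.0))
    ci_low, ci_high = np.tanh(z - half), np.tanh(z + half)
    return ConcordanceResult(
        float(rho_c), float(ci_low), float(ci_high), n, mcbride_class(rho_c)
    )


def mann_whitney(a, b) -> tuple[float, float]:
    """Mann-Whitney U test (two-sided) between two independent groups.

    Returns (U for group ``a``, two-sided p).  The p-value is exact (full
    enumeration of labelings) when the smaller group has <= 8 observations
    and there are no ties; otherwise the normal approximation with midrank
    tie correction and continuity correction is used.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(a.size, b.size) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def acceptance_check(
    stats_: DescriptiveStats, mean_limit: float = 10.0, sd_limit: float = 25.0
) -> AcceptanceVerdict:
    """Acceptance rule: |mean| <= mean_limit (accuracy) and SD <= sd_limit
    (precision); boundaries inclusive."""
    return AcceptanceVerdict(
        mean_ok=abs(stats_.mean) <= mean_limit,
        sd_ok=stats_.sd <= sd_limit,
    )
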