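"""Single-SNP baseline: simpleM-corrected noncentral-t power and sample size.

A sliding single-SNP regression ignores the other SNPs of the region, so the
pointwise level must be reduced to alpha_k = alpha / M_eff, where M_eff is
the effective number of independent tests obtained from the eigenvalues of
the theoretical SNP correlation matrix R (simpleM rule: the smallest number
of leading eigenvalues whose cumulative sum reaches 99.5 % of the total).
The t statistic of the single-SNP regression has n - 1 degrees of freedom
and noncentrality delta = (beta/sigma_e) sqrt(n).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "MeffResult",
    "meff",
    "noncentrality",
    "power_single_at",
    "samplesize_single",
    "SampleSizeSingle",
]


@dataclass
class MeffResult:
    m_eff: int
    eigenvalues: np.ndarray
    contribution_threshold: float


@dataclass
class SampleSizeSingle:
    n: int | None
    reached: bool
    alpha_k: float
    power_at_n: float


def meff(R: np.ndarray, threshold: float = 0.995) -> MeffResult:
    """Effective number of independent tests (simpleM).

    Eigenvalues of R are clipped at zero, sorted descending, and M_eff is
    the smallest m whose leading eigenvalues contribute at least
    ``threshold`` of the total sum.
    """
    R = np.asarray(R, float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValueError("R must be square")
    if not np.allclose(R, R.T, atol=1e-8):
        raise ValueError("R must be symmetric")
    ev = np.linalg.eigvalsh(R)[::-1]
    ev = np.clip(ev, 0.0, None)
    cum = np.cumsum(ev) / ev.sum()
    m = int(np.searchsorted(cum, threshold) + 1)
    m = min(m, R.shape[0])
    return MeffResult(m_eff=m, eigenvalues=ev, contribution_threshold=threshold)


def noncentrality(beta_over_sigma: float, n: int) -> float:
    """Noncentrality delta = (beta/sigma_e) * sqrt(n) of the single-SNP t-test."""
    return beta_over_sigma * np.sqrt(n)


def power_single_at(n: int, delta: float, alpha_k: float) -> float:
    """Two-sided power of the noncentral-t test with n - 1 df.

    pi = Pr(T >= t_{1-a/2}) + Pr(T < t_{a/2}) for T ~ t(n-1, ncp=delta).
    The lower tail is evaluated through the noncentrality-sign symmetry
    Pr(T_{df, d} < q) = Pr(T_{df, -d} > -q), which is exact and avoids a
    scipy/Boost NaN for negative quantiles at moderate ncp.
    """
    if n < 3:
        raise ValueError("n must be >= 3")
    if not 0.0 < alpha_k < 1.0:
        raise ValueError("alpha_k must lie in (0, 1)")
    df = n - 1
    tcrit = stats.t.ppf(1.0 - alpha_k / 2.0, df)
    upper = stats.nct.sf(tcrit, df, delta)
    lower = stats.nct.sf(tcrit, df, -delta)
    return float(upper + lower)


def samplesize_single(
    kappa: int,
    h2: float,
    alpha: float,
    m_eff: int,
    power_target: float = 0.8,
    n_max: int = 5000,
) -> SampleSizeSingle:
    """Smallest n with single-SNP power >= target at alpha_k = alpha / M_eff.

    The per-signal relative effect is sqrt(h2 / (kappa (1 - h2))); power is
    monotone in n for fixed effect and level, so integer bisection applies.
    An unreachable target at ``n_max`` is reported as a failure state, not
    raised.
    """
    if not 0.0 < power_target < 1.0:
        raise ValueError("power_target must lie in (0, 1)")
    alpha_k = alpha / m_eff
    b = np.sqrt(h2 / (kappa * (1.0 - h2)))

    def pw(n: int) -> float:
        return power_single_at(n, noncentrality(b, n), alpha_k)

    p_max = pw(n_max)
    if p_max < power_target:
        return SampleSizeSingle(n=None, reached=False, alpha_k=alpha_k, power_at_n=p_max)
    lo, hi = 3, n_max
    while lo < hi:
        mid = (lo + hi) // 2
        if pw(mid) >= power_target:
            hi = mid
        else:
            lo = mid + 1
    return SampleSizeSingle(n=lo, reached=True, alpha_k=alpha_k, power_at_n=pw(lo))
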