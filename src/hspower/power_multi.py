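"""Power of the local z-test in the multi-SNP (SNP-BLUP / ridge) model.

All p SNPs of the region are fitted jointly with a ridge penalty lambda.
The test statistic for SNP k, T_k = beta_hat_k / SD(beta_hat_k), is
approximately normal with unit variance and mean

    mu_k = sqrt(n)/sigma_e * {(R + lambda/n I)^-1 R beta}_k
           / sqrt{ (R + lambda/n I)^-1 R (R + lambda/n I)^-1 }_kk

where R is the theoretical SNP correlation matrix of the planned progeny
population.  Only the relative effects beta/sigma_e enter, so sigma_e = 1 is
used throughout.  Assuming kappa QTL signals of equal variance contribution
and regional heritability h2, each signal has relative effect

    beta/sigma_e = sqrt( h2 / (kappa (1 - h2)) )

and the design-stage shrinkage is the Hoerl value lambda = p (1 - h2) / h2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, stats

__all__ = [
    "EffectSpec",
    "PowerResult",
    "shrinkage_lambda",
    "effect_spec",
    "zscore_mean",
    "power_at",
    "RidgePowerKernel",
]


@dataclass
class EffectSpec:
    """Relative QTL effects placed at kappa positions of the retained loci."""

    qtl_indices: np.ndarray
    beta_over_sigma: float
    h2: float
    kappa: int

    def beta_vector(self, p: int) -> np.ndarray:
        beta = np.zeros(p)
        beta[self.qtl_indices] = self.beta_over_sigma
        return beta


@dataclass
class PowerResult:
    """Per-QTL distribution means and power at a given sample size."""

    mu: np.ndarray
    power: np.ndarray
    n: int
    lam: float


def shrinkage_lambda(p: int, h2: float) -> float:
    """Design-stage ridge penalty lambda = p (1 - h2) / h2 (Hoerl)."""
    if not 0.0 < h2 < 1.0:
        raise ValueError(f"h2 must lie in (0, 1), got {h2}")
    if p < 1:
        raise ValueError("p must be >= 1")
    return p * (1.0 - h2) / h2


def effect_spec(kappa: int, h2: float, qtl_indices) -> EffectSpec:
    """Equal relative effect sqrt(h2 / (kappa (1 - h2))) at kappa QTL positions."""
    if not 0.0 < h2 < 1.0:
        raise ValueError(f"h2 must lie in (0, 1), got {h2}")
    idx = np.asarray(qtl_indices, int)
    if idx.ndim != 1 or idx.size != kappa:
        raise ValueError("qtl_indices must be a flat vector of length kappa")
    if np.unique(idx).size != idx.size:
        raise ValueError("qtl_indices must be distinct")
    b = np.sqrt(h2 / (kappa * (1.0 - h2)))
    return EffectSpec(qtl_indices=idx, beta_over_sigma=b, h2=h2, kappa=kappa)


def zscore_mean(R: np.ndarray, effect: EffectSpec, n: int, lam: float) -> np.ndarray:
    """Mean mu_k of the ridge z-score under the alternative, for every SNP.

    Solved via a symmetric factorization of A = R + (lambda/n) I; no
    explicit inverse is formed.
    """
    R = np.asarray(R, float)
    p = R.shape[0]
    if n < 1:
        raise ValueError("n must be >= 1")
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    beta = effect.beta_vector(p)
    A = R + (lam / n) * np.eye(p)
    try:
        cf = linalg.cho_factor(A, lower=True)
        AinvR = linalg.cho_solve(cf, R)          # A^-1 R
        num = AinvR @ beta                        # A^-1 R beta
        M = linalg.cho_solve(cf, AinvR.T)         # A^-1 (A^-1 R)' = A^-1 R A^-1
    except linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "R + (lambda/n) I is numerically singular; increase lambda or "
            "repair R"
        ) from exc
    den = np.sqrt(np.clip(np.diag(M), 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        mu = np.sqrt(n) * num / den
    return np.where(den > 0, mu, 0.0)


def power_at(mu_k: float | np.ndarray, alpha: float) -> float | np.ndarray:
    """Two-sided power of the normal(mu, 1) z-test at level alpha.

    pi = 1 - Phi(z_{1-a/2} - mu) + Phi(z_{a/2} - mu); equals alpha under the
    null (mu = 0) and increases to 1 with |mu|.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    mu_k = np.asarray(mu_k, float)
    pw = stats.norm.sf(z - mu_k) + stats.norm.cdf(-z - mu_k)
    return float(pw) if pw.ndim == 0 else pw


class RidgePowerKernel:
    """Fast repeated evaluation of mu_k over many (n, QTL-set) pairs.

    Diagonalizes R once (R = Q diag(e) Q'); then for any shrinkage c = lam/n

        {A^-1 R b}_k        = sum_i Q_ki e_i/(e_i + c) (Q'b)_i
        {A^-1 R A^-1}_kk    = sum_i Q_ki^2 e_i/(e_i + c)^2

    which makes each power evaluation O(p * kappa).  Numerically identical
    (to solver tolerance) to :func:`zscore_mean`; used inside the sample-size
    bisection where thousands of evaluations are needed.
    """

    def __init__(self, R: np.ndarray):
        R = np.asarray(R, float)
        e, Q = np.linalg.eigh(R)
        self.evals = np.clip(e, 0.0, None)
        self.Q = Q
        self.p = R.shape[0]

    def mu(self, qtl_indices: np.ndarray, beta_over_sigma: float, n: int, lam: float) -> np.ndarray:
        c = lam / n
        g = self.evals / (self.evals + c)
        beta = np.zeros(self.p)
        beta[qtl_indices] = beta_over_sigma
        Qb = self.Q.T @ beta
        rows = self.Q[qtl_indices, :]
        num = rows @ (g * Qb)
        den = np.sqrt(rows**2 @ (self.evals / (self.evals + c) ** 2))
        with np.errstate(divide="ignore", invalid="ignore"):
            mu = np.sqrt(n) * num / den
        return np.where(den > 0, mu, 0.0)

    def min_power(self, qtl_indices, beta_over_sigma: float, n: int, lam: float, alpha: float) -> float:
        mu = self.mu(np.asarray(qtl_indices, int), beta_over_sigma, n, lam)
        return float(np.min(power_at(mu, alpha)))


def power_result(R: np.ndarray, effect: EffectSpec, n: int, lam: float, alpha: float) -> PowerResult:
    """Convenience wrapper: mu and power at the QTL indices for one n."""
    mu_all = zscore_mean(R, effect, n, lam)
    mu = mu_all[effect.qtl_indices]
    return PowerResult(mu=mu, power=np.asarray(power_at(mu, alpha)), n=n, lam=lam)
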