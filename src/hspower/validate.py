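"""Association analysis at the designed sample size, and its validation.

Fits the multi-SNP ridge (SNP-BLUP) model and the single-SNP OLS scan to
progeny data, tests SNP effects, applies Benjamini-Hochberg correction to
the single-SNP p-values (the multi-SNP p-values are left unadjusted), and
scores detections against the true QTL positions using a genetic-map window
(a significant SNP within +/- 0.01 cM of a QTL counts as a true positive).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, stats
from statsmodels.stats.multitest import multipletests

from .covariance import GeneticMap

__all__ = [
    "AssociationResult",
    "RocSummary",
    "ridge_fit",
    "ridge_test",
    "single_snp_scan",
    "score_detections",
    "roc_curve",
]


@dataclass
class AssociationResult:
    beta_hat: np.ndarray
    test_stat: np.ndarray
    p_values: np.ndarray
    p_adjusted: np.ndarray | None
    model: str
    dropped_columns: np.ndarray | None = None


@dataclass
class RocSummary:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    window_cM: float = 0.01
    model: str = ""


def ridge_fit(X_model: np.ndarray, y: np.ndarray, lam: float) -> np.ndarray:
    """Exact ridge solution beta_hat = (X'X + lambda I)^-1 X'y (SPD solve)."""
    X = np.asarray(X_model, float)
    y = np.asarray(y, float)
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y differ in length")
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    p = X.shape[1]
    A = X.T @ X + lam * np.eye(p)
    cf = linalg.cho_factor(A, lower=True)
    return linalg.cho_solve(cf, X.T @ y)


def ridge_test(
    X_model: np.ndarray,
    y: np.ndarray,
    beta_hat: np.ndarray,
    lam: float,
    sigma2_e: float | None = None,
) -> AssociationResult:
    """z-tests of the ridge coefficients, T_k = beta_hat_k / SD(beta_hat_k).

    V(beta_hat) = (X'X + lam I)^-1 X'X (X'X + lam I)^-1 sigma_e^2.  When
    ``sigma2_e`` is not supplied it is estimated from the ridge residuals
    with the effective-degrees-of-freedom correction df = trace of the ridge
    hat matrix (the design-time alternative is a REML estimate, which this
    module does not attempt).  P-values are two-sided normal, unadjusted.
    """
    X = np.asarray(X_model, float)
    y = np.asarray(y, float)
    n, p = X.shape
    A = X.T @ X + lam * np.eye(p)
    cf = linalg.cho_factor(A, lower=True)
    AinvXtX = linalg.cho_solve(cf, X.T @ X)
    if sigma2_e is None:
        df_ridge = float(np.trace(AinvXtX))
        if n <= df_ridge:
            raise ValueError(
                f"n={n} does not exceed the ridge effective df {df_ridge:.1f}"
            )
        resid = y - X @ beta_hat
        sigma2_e = float(resid @ resid) / (n - df_ridge)
    V = linalg.cho_solve(cf, AinvXtX.T) * sigma2_e  # A^-1 X'X A^-1 s2
    sd = np.sqrt(np.clip(np.diag(V), 1e-300, None))
    T = beta_hat / sd
    pvals = 2.0 * stats.norm.sf(np.abs(T))
    return AssociationResult(
        beta_hat=beta_hat, test_stat=T, p_values=pvals, p_adjusted=None, model="multi"
    )


def single_snp_scan(X_model: np.ndarray, y: np.ndarray) -> AssociationResult:
    """Per-SNP OLS with t-tests (n - 1 df) and Benjamini-Hochberg adjustment.

    Zero-variance columns are excluded from testing and reported; their
    entries are NaN in the outputs.
    """
    X = np.asarray(X_model, float)
    y = np.asarray(y, float)
    n, p = X.shape
    ss = (X**2).sum(axis=0)
    ok = ss > 0
    beta = np.full(p, np.nan)
    T = np.full(p, np.nan)
    pv = np.full(p, np.nan)
    Xok = X[:, ok]
    ssk = ss[ok]
    b = (Xok.T @ y) / ssk
    resid_ss = (y @ y) - b**2 * ssk
    df = n - 1
    s2 = np.clip(resid_ss, 1e-300, None) / df
    se = np.sqrt(s2 / ssk)
    t = b / se
    beta[ok] = b
    T[ok] = t
    pv[ok] = 2.0 * stats.t.sf(np.abs(t), df)
    padj = np.full(p, np.nan)
    if ok.any():
        padj[ok] = multipletests(pv[ok], method="fdr_bh")[1]
    return AssociationResult(
        beta_hat=beta,
        test_stat=T,
        p_values=pv,
        p_adjusted=padj,
        model="single",
        dropped_columns=np.flatnonzero(~ok),
    )


def _qtl_windows(
    qtl_indices: np.ndarray, gmap: GeneticMap, window_cM: float
) -> np.ndarray:
    """Boolean mask over SNPs lying within +/- window of any QTL (merged)."""
    pos = gmap.position_cM
    mask = np.zeros(gmap.p, bool)
    for q in qtl_indices:
        mask |= np.abs(pos - pos[q]) <= window_cM + 1e-12
    return mask


def score_detections(
    result: AssociationResult,
    qtl_indices,
    gmap: GeneticMap,
    window_cM: float = 0.01,
    alpha: float = 0.05,
    use_adjusted: bool | None = None,
) -> tuple[float, float]:
    """(TPR, FPR) of the significant SNPs against map windows around QTL.

    A QTL counts as detected when at least one significant SNP lies within
    +/- ``window_cM`` of it; TPR = detected QTL / kappa.  Significant SNPs
    outside every window are false positives; FPR = their count over the
    number of SNPs outside all windows.  Overlapping windows merge
    naturally through the mask.
    """
    qtl_indices = np.asarray(qtl_indices, int)
    if use_adjusted is None:
        use_adjusted = result.p_adjusted is not None
    pv = result.p_adjusted if use_adjusted else result.p_values
    sig = np.asarray(pv) < alpha
    sig &= ~np.isnan(pv)
    pos = gmap.position_cM
    detected = 0
    for q in qtl_indices:
        in_window = np.abs(pos - pos[q]) <= window_cM + 1e-12
        if np.any(sig & in_window):
            detected += 1
    tpr = detected / len(qtl_indices)
    window_mask = _qtl_windows(qtl_indices, gmap, window_cM)
    outside = ~window_mask
    n_out = int(outside.sum())
    fpr = float((sig & outside).sum()) / n_out if n_out else 0.0
    return float(tpr), fpr


def roc_curve(
    result: AssociationResult,
    qtl_indices,
    gmap: GeneticMap,
    thresholds: np.ndarray | None = None,
    window_cM: float = 0.01,
) -> RocSummary:
    """TPR/FPR sweep over significance thresholds.

    The single-SNP model is swept on BH-adjusted p-values, the multi-SNP
    model on raw p-values.  Endpoints (0, 0) and (1, 1) are always included.
    """
    use_adj = result.p_adjusted is not None
    pv = np.asarray(result.p_adjusted if use_adj else result.p_values, float)
    if thresholds is None:
        finite = np.unique(pv[~np.isnan(pv)])
        thresholds = np.concatenate(([0.0], finite, [1.0 + 1e-12]))
    else:
        thresholds = np.sort(np.asarray(thresholds, float))
        if thresholds.size < 2:
            raise ValueError("need at least 2 thresholds")
    tpr = np.empty(thresholds.size)
    fpr = np.empty(thresholds.size)
    for i, t in enumerate(thresholds):
        tpr[i], fpr[i] = score_detections(
            result, qtl_indices, gmap, window_cM, alpha=t, use_adjusted=use_adj
        )
    order = np.argsort(fpr, kind="stable")
    return RocSummary(
        thresholds=thresholds,
        tpr=np.maximum.accumulate(tpr[order]),
        fpr=fpr[order],
        window_cM=window_cM,
        model=result.model,
    )
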