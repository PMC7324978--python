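"""Optimal-sample-size search for the multi-SNP model.

The QTL positions of a future fine-mapping experiment are unknown, so the
design criterion is evaluated over repeated random draws of kappa candidate
positions among the retained (segregating) loci.  For each draw, the
smallest n whose minimum per-QTL power reaches the target is found by
integer bisection over the n-range; the median over draws is proposed as
the final optimal sample size n_opt*.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .power_multi import RidgePowerKernel, effect_spec, shrinkage_lambda

__all__ = [
    "DesignSpec",
    "SampleSizeResult",
    "draw_qtl_positions",
    "n_opt_for_positions",
    "optimal_sample_size",
]


@dataclass
class DesignSpec:
    """Design parameters of the sample-size search."""

    kappa: int
    h2: float
    alpha: float = 0.01
    power_target: float = 0.8
    n_range: tuple[int, int] = (1, 5000)
    n_draws: int = 100
    seed: int = 0
    #: aggregate power over the kappa signals before thresholding;
    #: "min" requires every signal to be detectable, "mean" the average.
    criterion: str = "min"

    def __post_init__(self) -> None:
        if self.kappa < 1:
            raise ValueError("kappa must be >= 1")
        if not 0.0 < self.h2 < 1.0:
            raise ValueError("h2 must lie in (0, 1)")
        lo, hi = self.n_range
        if not (1 <= lo <= hi):
            raise ValueError("invalid n_range")
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")
        if self.criterion not in ("min", "mean"):
            raise ValueError("criterion must be 'min' or 'mean'")


@dataclass
class SampleSizeResult:
    """Per-draw optimal sample sizes and their aggregate."""

    n_opt_draws: np.ndarray          # float; NaN marks unreachable draws
    n_opt_star: int | None
    qtl_draws: list[np.ndarray]
    min_pair_correlation: np.ndarray
    n_failed: int
    spec: DesignSpec = field(repr=False, default=None)

    @property
    def failed_fraction(self) -> float:
        return self.n_failed / len(self.n_opt_draws)


def draw_qtl_positions(p_retained: int, kappa: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform sample of kappa distinct QTL positions among retained loci."""
    if kappa > p_retained:
        raise ValueError(f"kappa={kappa} exceeds the {p_retained} retained loci")
    return np.sort(rng.choice(p_retained, size=kappa, replace=False))


def _power_fn(kernel: RidgePowerKernel, spec: DesignSpec, qtl_indices: np.ndarray, lam: float, b: float):
    from .power_multi import power_at

    if spec.criterion == "min":
        def f(n: int) -> float:
            return kernel.min_power(qtl_indices, b, n, lam, spec.alpha)
    else:
        def f(n: int) -> float:
            mu = kernel.mu(qtl_indices, b, n, lam)
            return float(np.mean(power_at(mu, spec.alpha)))
    return f


def n_opt_for_positions(
    R: np.ndarray,
    spec: DesignSpec,
    qtl_indices,
    kernel: RidgePowerKernel | None = None,
    lam: float | None = None,
) -> int | None:
    """Minimal n whose aggregated QTL power reaches the target, or None.

    Integer bisection assumes the power criterion is monotone in n; this is
    verified on the bracketing endpoints and, if violated, the search falls
    back to a linear scan.
    """
    if kernel is None:
        kernel = RidgePowerKernel(R)
    qtl_indices = np.asarray(qtl_indices, int)
    if np.any((qtl_indices < 0) | (qtl_indices >= kernel.p)):
        raise IndexError("QTL indices out of range")
    if lam is None:
        lam = shrinkage_lambda(kernel.p, spec.h2)
    b = effect_spec(spec.kappa, spec.h2, qtl_indices).beta_over_sigma
    f = _power_fn(kernel, spec, qtl_indices, lam, b)
    n_lo, n_hi = spec.n_range
    p_lo, p_hi = f(n_lo), f(n_hi)
    if p_hi < spec.power_target:
        return None
    if p_lo > p_hi + 1e-12:  # monotonicity violated at the bracket
        for n in range(n_lo, n_hi + 1):
            if f(n) >= spec.power_target:
                return n
        return None
    lo, hi = n_lo, n_hi
    while lo < hi:
        mid = (lo + hi) // 2
        if f(mid) >= spec.power_target:
            hi = mid
        else:
            lo = mid + 1
    return lo


def _median_int(values: np.ndarray) -> int:
    """Median of integer draws; even counts round the middle-pair mean up."""
    v = np.sort(values)
    m = v.size
    if m % 2 == 1:
        return int(v[m // 2])
    return int(math.ceil(0.5 * (v[m // 2 - 1] + v[m // 2])))


def optimal_sample_size(R: np.ndarray, spec: DesignSpec) -> SampleSizeResult:
    """Repeat the QTL-position draw n_draws times and aggregate.

    Draw j uses a child generator seeded by (seed, j), so any subset of
    draws is reproducible in isolation.  Draws whose target is unreachable
    at n_max are excluded from the median and counted separately; if more
    than half fail, ``n_opt_star`` is None (report as "> n_max").
    """
    R = np.asarray(R, float)
    kernel = RidgePowerKernel(R)
    lam = shrinkage_lambda(kernel.p, spec.h2)
    n_opt = np.full(spec.n_draws, np.nan)
    qtl_draws: list[np.ndarray] = []
    min_corr = np.full(spec.n_draws, np.nan)
    for j in range(spec.n_draws):
        rng = np.random.default_rng([spec.seed, j])
        idx = draw_qtl_positions(kernel.p, spec.kappa, rng)
        qtl_draws.append(idx)
        if spec.kappa > 1:
            sub = R[np.ix_(idx, idx)]
            min_corr[j] = np.min(sub[~np.eye(spec.kappa, dtype=bool)])
        else:
            # most negative correlation of the QTL column: diagnostic for
            # linkage-phase blocks that inflate sample size
            col = np.delete(R[idx[0]], idx[0])
            min_corr[j] = np.min(col) if col.size else np.nan
        res = n_opt_for_positions(R, spec, idx, kernel=kernel, lam=lam)
        if res is not None:
            n_opt[j] = res
    ok = ~np.isnan(n_opt)
    n_failed = int((~ok).sum())
    if not ok.any():
        pmax = max(
            kernel.min_power(q, effect_spec(spec.kappa, spec.h2, q).beta_over_sigma,
                             spec.n_range[1], lam, spec.alpha)
            for q in qtl_draws
        )
        raise RuntimeError(
            f"target power {spec.power_target} unreachable at n_max="
            f"{spec.n_range[1]} for every draw (best achieved {pmax:.3f})"
        )
    n_star = _median_int(n_opt[ok]) if n_failed <= spec.n_draws / 2 else None
    return SampleSizeResult(
        n_opt_draws=n_opt,
        n_opt_star=n_star,
        qtl_draws=qtl_draws,
        min_pair_correlation=min_corr,
        n_failed=n_failed,
        spec=spec,
    )
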