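"""Theoretical between-SNP covariance for paternal half-sib families.

Progeny of a sire ``s`` and a random dam carry one paternal and one maternal
gamete.  With additive genotype codes ``X in {1, 0, -1}`` (A/A, A/B, B/B),
the covariance between SNPs ``k`` and ``l`` over the whole half-sib
population decomposes into a maternal gametic-LD term, a sire-phase term and
a between-family term:

    K_kl = D^d_kl + sum_s w_s D^s_kl
           + sum_s w_s E^s_k E^s_l - (sum_s w_s E^s_k)(sum_s w_s E^s_l)

where ``D^d`` is the gametic LD of the dam population, ``D^s_kl`` equals
``+(1-2*theta_kl)/4`` for a sire carrying the coupling diplotype (A-A / B-B),
``-(1-2*theta_kl)/4`` for repulsion (A-B / B-A) and 0 whenever the sire is
homozygous at either locus, and ``E^s_k`` is the expectation of the
paternally inherited half-code (+1/2 for A/A, 0 for A/B, -1/2 for B/B).
``theta_kl`` is the recombination rate between the loci and ``w_s = n_s/n``
are family weights.  The variance reduces to

    K_kk = p_k (1 - p_k) + 1/4 - (sum_s w_s E^s_k)^2

with ``p_k`` the maternal allele frequency.  Scaling ``K`` to unit diagonal
gives the correlation matrix ``R`` that the power calculations consume in
place of the (unknown, future) observed genotype correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "GeneticMap",
    "SireDiplotypes",
    "DamPopulation",
    "FamilyWeights",
    "RegionCorrelation",
    "recombination_rate",
    "theta_matrix",
    "sire_ld_term",
    "sire_expectation",
    "maternal_ld_from_haplotypes",
    "covariance_matrix",
    "correlation_matrix",
    "orient_major",
]

#: default physical-to-genetic conversion: 1 Mbp corresponds to 1 cM
CM_PER_BP = 1e-6


@dataclass
class GeneticMap:
    """Marker map for the target region.

    Parameters
    ----------
    snp_ids
        One identifier per SNP.
    position_cM
        Map positions in centimorgan, monotone non-decreasing.  May be
        ``None`` if only physical positions are known; they are then derived
        from ``position_bp`` at 1 cM per Mbp.
    position_bp
        Optional physical positions (1-based).
    """

    snp_ids: Sequence[str]
    position_cM: np.ndarray | None = None
    position_bp: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.position_cM is None:
            if self.position_bp is None:
                raise ValueError(
                    "GeneticMap needs position_cM or position_bp; derive cM "
                    "from bp at 1 Mbp = 1 cM if only physical positions exist"
                )
            self.position_cM = np.asarray(self.position_bp, float) * CM_PER_BP
        self.position_cM = np.asarray(self.position_cM, float)
        if self.position_bp is not None:
            self.position_bp = np.asarray(self.position_bp)
        if len(self.snp_ids) != self.p:
            raise ValueError("snp_ids and positions differ in length")
        if np.any(~np.isfinite(self.position_cM)) or np.any(self.position_cM < 0):
            raise ValueError("cM positions must be finite and >= 0")
        if np.any(np.diff(self.position_cM) < 0):
            raise ValueError("map positions must be sorted (non-decreasing)")

    @property
    def p(self) -> int:
        return len(self.position_cM)

    def subset(self, indices: np.ndarray) -> "GeneticMap":
        ids = [self.snp_ids[i] for i in indices]
        bp = None if self.position_bp is None else self.position_bp[indices]
        return GeneticMap(ids, self.position_cM[indices], bp)


@dataclass
class SireDiplotypes:
    """Phased two-haplotype records of the N sires over p SNPs.

    ``hap1`` and ``hap2`` are (N, p) binary arrays; allele 1 is the
    reference ("A") allele, conventionally the major allele.
    """

    sire_ids: Sequence[str]
    hap1: np.ndarray
    hap2: np.ndarray

    def __post_init__(self) -> None:
        self.hap1 = np.asarray(self.hap1)
        self.hap2 = np.asarray(self.hap2)
        if self.hap1.shape != self.hap2.shape or self.hap1.ndim != 2:
            raise ValueError("hap1/hap2 must be (N, p) arrays of equal shape")
        if len(self.sire_ids) != self.hap1.shape[0]:
            raise ValueError("number of sire ids does not match haplotypes")
        for h in (self.hap1, self.hap2):
            vals = np.unique(h)
            if not np.all(np.isin(vals, [0, 1])):
                raise ValueError("haplotype alleles must be binary 0/1")

    @property
    def n_sires(self) -> int:
        return self.hap1.shape[0]

    @property
    def p(self) -> int:
        return self.hap1.shape[1]

    def phase_vector(self) -> np.ndarray:
        """(N, p) array ``a`` with a = hap1 - hap2 in {-1, 0, +1}.

        ``a_k a_l`` is +1 for a coupling double heterozygote, -1 for
        repulsion and 0 when either locus is homozygous, which makes the
        sire LD term ``D^s_kl = a_k a_l (1 - 2 theta_kl) / 4``.
        """
        return self.hap1.astype(float) - self.hap2.astype(float)

    def expectation_matrix(self) -> np.ndarray:
        """(N, p) array of E(X_paternal | sire) in {-1/2, 0, +1/2}."""
        return 0.5 * (self.hap1 + self.hap2 - 1.0)


@dataclass
class DamPopulation:
    """Maternal allele frequencies and gametic LD of the dam population."""

    maternal_freq: np.ndarray
    maternal_ld: np.ndarray

    def __post_init__(self) -> None:
        self.maternal_freq = np.asarray(self.maternal_freq, float)
        self.maternal_ld = np.asarray(self.maternal_ld, float)
        p = self.maternal_freq.shape[0]
        if self.maternal_ld.shape != (p, p):
            raise ValueError("maternal_ld must be (p, p)")
        if np.any((self.maternal_freq < 0) | (self.maternal_freq > 1)):
            raise ValueError("maternal frequencies must lie in [0, 1]")
        if not np.allclose(self.maternal_ld, self.maternal_ld.T, atol=1e-10):
            raise ValueError("maternal_ld must be symmetric")
        if np.any(np.abs(self.maternal_ld) > 0.25 + 1e-9):
            raise ValueError("|gametic LD| cannot exceed 0.25")

    @property
    def p(self) -> int:
        return self.maternal_freq.shape[0]


@dataclass
class FamilyWeights:
    """Normalized family weights w_s = n_s / n approximating Pr(sire s)."""

    w: np.ndarray

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, float)
        if np.any(self.w < 0):
            raise ValueError("family weights must be non-negative")
        s = self.w.sum()
        if s <= 0:
            raise ValueError("family weights must sum to a positive value")
        self.w = self.w / s

    @classmethod
    def equal(cls, n_families: int) -> "FamilyWeights":
        return cls(np.full(n_families, 1.0 / n_families))

    @classmethod
    def from_sizes(cls, sizes: Sequence[int]) -> "FamilyWeights":
        return cls(np.asarray(sizes, float))


@dataclass
class RegionCorrelation:
    """Covariance K and correlation R over the retained (polymorphic) loci."""

    K: np.ndarray
    R: np.ndarray
    kept_indices: np.ndarray
    dropped_indices: np.ndarray = field(default_factory=lambda: np.array([], int))

    @property
    def p_retained(self) -> int:
        return self.R.shape[0]


def recombination_rate(gmap: GeneticMap, k: int, l: int) -> float:
    """Recombination rate between SNPs ``k`` and ``l`` via Haldane's map function.

    theta = (1 - exp(-2 d)) / 2 with d the map distance in Morgan; theta is
    0 at zero distance and approaches 1/2 for unlinked loci.
    """
    p = gmap.p
    if not (0 <= k < p and 0 <= l < p):
        raise IndexError(f"SNP indices ({k}, {l}) out of range for p={p}")
    d_morgan = abs(gmap.position_cM[k] - gmap.position_cM[l]) / 100.0
    return 0.5 * (1.0 - np.exp(-2.0 * d_morgan))


def theta_matrix(gmap: GeneticMap) -> np.ndarray:
    """Pairwise Haldane recombination rates as a (p, p) matrix."""
    d = np.abs(gmap.position_cM[:, None] - gmap.position_cM[None, :]) / 100.0
    return 0.5 * (1.0 - np.exp(-2.0 * d))


def sire_ld_term(hap1_kl: Sequence[int], hap2_kl: Sequence[int], theta: float) -> float:
    """Paternal LD contribution D^s_kl of one sire for one SNP pair.

    ``hap1_kl``/``hap2_kl`` hold the two alleles of the first and second
    haplotype at SNPs (k, l).  Coupling double heterozygotes (A-A with B-B)
    contribute +(1 - 2 theta)/4, repulsion (A-B with B-A) the negative, and
    any homozygous locus makes the term vanish.
    """
    if not 0.0 <= theta <= 0.5:
        raise ValueError("theta must lie in [0, 0.5]")
    a_k = hap1_kl[0] - hap2_kl[0]
    a_l = hap1_kl[1] - hap2_kl[1]
    return 0.25 * (1.0 - 2.0 * theta) * a_k * a_l


def sire_expectation(allele1: int, allele2: int) -> float:
    """E(paternal half-code | sire genotype): +1/2 (A/A), 0 (A/B), -1/2 (B/B)."""
    return 0.5 * (allele1 + allele2 - 1.0)


def maternal_ld_from_haplotypes(haplotypes: np.ndarray) -> DamPopulation:
    """Estimate dam allele frequencies and gametic LD from a haplotype sample.

    Parameters
    ----------
    haplotypes
        (n_hap, p) binary matrix, one row per gamete.  The plug-in estimate
        is ``D_kl = f_AB(k, l) - p_k p_l`` with joint two-locus gamete
        frequencies ``f_AB``; the diagonal is ``p_k (1 - p_k)``.
    """
    H = np.asarray(haplotypes, float)
    if H.ndim != 2 or H.shape[0] < 2:
        raise ValueError("need a (n_hap >= 2, p) haplotype matrix")
    n = H.shape[0]
    p_k = H.mean(axis=0)
    D = (H.T @ H) / n - np.outer(p_k, p_k)
    # force the exact binomial diagonal (guards against fp drift)
    np.fill_diagonal(D, p_k * (1.0 - p_k))
    D = 0.5 * (D + D.T)
    return DamPopulation(maternal_freq=p_k, maternal_ld=D)


def covariance_matrix(
    sires: SireDiplotypes,
    gmap: GeneticMap,
    dams: DamPopulation,
    weights: FamilyWeights | None = None,
) -> np.ndarray:
    """Theoretical covariance K of progeny genotype codes.

    Vectorized over all SNP pairs: with phase vectors ``a_s`` and paternal
    expectations ``E_s`` per sire,

        K = D^d + (1 - 2 Theta)/4 * sum_s w_s a_s a_s'
            + sum_s w_s E_s E_s' - Ebar Ebar',   Ebar = sum_s w_s E_s.

    The diagonal then automatically equals p_k(1-p_k) + 1/4 - Ebar_k^2
    because a_k^2/4 + E_k^2 = 1/4 for every genotype.
    """
    p = sires.p
    if gmap.p != p or dams.p != p:
        raise ValueError(
            f"dimension mismatch: sires p={p}, map p={gmap.p}, dams p={dams.p}"
        )
    if weights is None:
        weights = FamilyWeights.equal(sires.n_sires)
    w = weights.w
    if w.shape[0] != sires.n_sires:
        raise ValueError("one weight per sire required")

    theta = theta_matrix(gmap)
    a = sires.phase_vector()
    E = sires.expectation_matrix()
    paternal_ld = 0.25 * (1.0 - 2.0 * theta) * ((a * w[:, None]).T @ a)
    Ebar = w @ E
    between = (E * w[:, None]).T @ E - np.outer(Ebar, Ebar)
    K = dams.maternal_ld + paternal_ld + between
    return 0.5 * (K + K.T)


def correlation_matrix(K: np.ndarray, drop_threshold: float = 1e-12) -> RegionCorrelation:
    """Scale K to a correlation matrix, dropping zero-variance loci.

    Loci whose variance ``K_kk`` does not exceed ``drop_threshold`` are
    removed and reported in ``dropped_indices``; the survivors keep their
    original indices in ``kept_indices``.
    """
    K = np.asarray(K, float)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise ValueError("K must be square")
    if not np.allclose(K, K.T, atol=1e-8):
        raise ValueError("K must be symmetric")
    var = np.diag(K)
    kept = np.flatnonzero(var > drop_threshold)
    if kept.size == 0:
        raise ValueError("all loci are monomorphic (zero variance)")
    dropped = np.setdiff1d(np.arange(K.shape[0]), kept)
    Kk = K[np.ix_(kept, kept)]
    d = np.sqrt(np.diag(Kk))
    R = Kk / np.outer(d, d)
    np.fill_diagonal(R, 1.0)
    R = 0.5 * (R + R.T)
    return RegionCorrelation(K=Kk, R=R, kept_indices=kept, dropped_indices=dropped)


def region_correlation(
    sires: SireDiplotypes,
    gmap: GeneticMap,
    dams: DamPopulation,
    weights: FamilyWeights | None = None,
    drop_threshold: float = 1e-12,
) -> RegionCorrelation:
    """Covariance and correlation of the region in one call."""
    K = covariance_matrix(sires, gmap, dams, weights)
    return correlation_matrix(K, drop_threshold=drop_threshold)


def orient_major(haplotypes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Recode alleles so that 1 is the major allele at every SNP.

    Returns the re-oriented matrix and a boolean array marking the SNPs that
    were flipped, so downstream genotype coding stays consistent.
    """
    H = np.asarray(haplotypes)
    flipped = H.mean(axis=0) < 0.5
    out = np.where(flipped[None, :], 1 - H, H)
    return out, flipped
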