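import numpy as np
import pytest

from hspower.covariance import (
    DamPopulation,
    GeneticMap,
    SireDiplotypes,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def uniform_map():
    """Map factory: p SNPs evenly spread over a given cM length."""

    def make(p: int, length_cM: float = 1.0) -> GeneticMap:
        return GeneticMap(
            [f"snp{i+1}" for i in range(p)],
            np.linspace(0.0, length_cM, p),
        )

    return make


@pytest.fixture
def two_snp_coupling_sire():
    """Single sire, coupling double heterozygote (A-A / B-B) at 2 SNPs."""
    return SireDiplotypes(["s1"], hap1=[[1, 1]], hap2=[[0, 0]])


def dam_pool_from_counts(haplotypes: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """Explicit gamete population with known haplotype frequencies."""
    return np.repeat(np.asarray(haplotypes, np.int8), counts, axis=0)


@pytest.fixture
def exact_dams():
    """DamPopulation factory from exact frequencies and an LD matrix."""

    def make(freq, ld) -> DamPopulation:
        return DamPopulation(np.asarray(freq, float), np.asarray(ld, float))

    return make
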