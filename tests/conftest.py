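import numpy as np
import pytest

from tdsgwas.synthetic_cohorts import (
    GenotypeMatrix,
    PartyDataset,
    PhenotypeVector,
    ScenarioSpec,
    SimulationParams,
    assemble_scenario,
    simulate_genotypes,
    simulate_liability_phenotypes,
)


def make_party(
    party_id: str = "A",
    n_individuals: int = 60,
    n_snps: int = 10,
    seed: int = 0,
    maf_low: float = 0.15,
    maf_high: float = 0.5,
    case_fraction: float = 0.5,
) -> PartyDataset:
    """A small random party dataset with a null (genotype-free) phenotype."""
    rng = np.random.default_rng(seed)
    mafs = rng.uniform(maf_low, maf_high, n_snps)
    values = rng.binomial(2, mafs, size=(n_individuals, n_snps))
    labels = np.zeros(n_individuals, dtype=int)
    labels[: int(round(case_fraction * n_individuals))] = 1
    labels = rng.permutation(labels)
    geno = GenotypeMatrix(
        values=values,
        snp_ids=[f"snp{j}" for j in range(n_snps)],
        individual_ids=[f"{party_id}_ind{i}" for i in range(n_individuals)],
    )
    return PartyDataset(party_id, geno, PhenotypeVector(labels=labels))


@pytest.fixture
def small_party() -> PartyDataset:
    return make_party()


@pytest.fixture
def two_parties() -> list[PartyDataset]:
    """Two aligned parties over the same SNP panel (disjoint individuals)."""
    a = make_party("A", n_individuals=80, seed=1)
    b = make_party("B", n_individuals=80, seed=2)
    return [a, b]


@pytest.fixture
def small_study() -> tuple[list[PartyDataset], SimulationParams]:
    """A compact synthetic two-party study with real genetic signal."""
    sim = SimulationParams(
        n_snps=120, n_individuals=320, n_causal=6, heritability=0.6, seed=42
    )
    g = simulate_genotypes(sim)
    ph, _ = simulate_liability_phenotypes(g, sim, n_cases=160)
    parties = assemble_scenario(
        g, ph, ScenarioSpec(((80, 80), (80, 80))), seed=7
    )
    return parties, sim
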