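"""Synthetic case-control cohorts.

Genotypes are drawn under Hardy-Weinberg equilibrium with per-SNP minor
allele frequencies sampled uniformly from a configurable band (default
[0.1, 0.5], so the usual MAF >= 0.1 filter holds by construction).  Binary
phenotypes follow a liability-threshold model: a sparse set of causal SNPs
contributes additively to a latent liability with variance equal to the
heritability, independent Gaussian noise supplies the rest, and the
top-ranked individuals by liability are assigned case status so that exact
case counts can be honoured.  A pooled cohort is then partitioned without
replacement into party datasets according to a scenario that fixes each
party's case and control counts.

SNPs are simulated independently (no linkage disequilibrium) and there is no
population structure, relatedness or missingness; see ``docs/methods.md``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from tdsgwas._rng import substream
from tdsgwas.errors import ConfigurationError, ScenarioError

__all__ = [
    "GenotypeMatrix",
    "PhenotypeVector",
    "PartyDataset",
    "SimulationParams",
    "ScenarioSpec",
    "SCENARIO_PRESETS",
    "simulate_genotypes",
    "simulate_liability_phenotypes",
    "assemble_scenario",
]


@dataclass
class GenotypeMatrix:
    """Minor-allele-count matrix (individuals x SNPs), entries in {0, 1, 2}.

    ``chrom`` optionally tags each SNP with an (opaque) chromosome label used
    only to keep protocol batches chromosome-homogeneous.  ``maf`` carries the
    simulation-truth allele frequencies when the matrix was generated here; it
    is not part of the data contract and is ``None`` for file-loaded data.
    """

    values: np.ndarray
    snp_ids: list[str]
    individual_ids: list[str]
    chrom: Optional[list[str]] = None
    maf: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ConfigurationError("genotype values must be a 2-D matrix")
        if not np.isin(self.values, (0, 1, 2)).all():
            raise ConfigurationError("genotype entries must be 0, 1 or 2")
        self.values = self.values.astype(np.int8, copy=False)
        self.snp_ids = [str(s) for s in self.snp_ids]
        self.individual_ids = [str(s) for s in self.individual_ids]
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ConfigurationError("duplicate snp_ids")
        if len(set(self.individual_ids)) != len(self.individual_ids):
            raise ConfigurationError("duplicate individual_ids")
        n_ind, n_snp = self.values.shape
        if n_ind != len(self.individual_ids) or n_snp != len(self.snp_ids):
            raise ConfigurationError(
                f"shape {self.values.shape} does not match "
                f"{len(self.individual_ids)} individuals x {len(self.snp_ids)} SNPs"
            )
        if self.chrom is not None and len(self.chrom) != n_snp:
            raise ConfigurationError("chrom tags must align with snp_ids")

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]

    def take_individuals(self, indices: Sequence[int]) -> "GenotypeMatrix":
        idx = np.asarray(indices)
        return GenotypeMatrix(
            values=self.values[idx],
            snp_ids=list(self.snp_ids),
            individual_ids=[self.individual_ids[i] for i in idx],
            chrom=None if self.chrom is None else list(self.chrom),
            maf=self.maf,
        )

    def take_snps(self, snp_ids: Sequence[str]) -> "GenotypeMatrix":
        pos = {s: j for j, s in enumerate(self.snp_ids)}
        try:
            idx = np.array([pos[s] for s in snp_ids], dtype=int)
        except KeyError as exc:
            raise ConfigurationError(f"unknown snp_id {exc.args[0]!r}") from exc
        return GenotypeMatrix(
            values=self.values[:, idx],
            snp_ids=[self.snp_ids[j] for j in idx],
            individual_ids=list(self.individual_ids),
            chrom=None if self.chrom is None else [self.chrom[j] for j in idx],
            maf=None if self.maf is None else self.maf[idx],
        )


@dataclass
class PhenotypeVector:
    """Binary case (1) / control (0) labels aligned to a genotype matrix."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 1 or not np.isin(self.labels, (0, 1)).all():
            raise ConfigurationError("phenotype labels must be a 1-D 0/1 vector")
        self.labels = self.labels.astype(np.int8, copy=False)

    @property
    def n(self) -> int:
        return self.labels.shape[0]

    @property
    def n_cases(self) -> int:
        return int(self.labels.sum())

    @property
    def n_controls(self) -> int:
        return int(self.n - self.labels.sum())


@dataclass
class PartyDataset:
    """One collaborating party's genotype matrix plus phenotype vector."""

    party_id: str
    genotypes: GenotypeMatrix
    phenotypes: PhenotypeVector

    def __post_init__(self) -> None:
        if self.phenotypes.n != self.genotypes.n_individuals:
            raise ConfigurationError(
                f"party {self.party_id!r}: {self.phenotypes.n} phenotypes for "
                f"{self.genotypes.n_individuals} individuals"
            )

    @property
    def n_individuals(self) -> int:
        return self.genotypes.n_individuals

    @property
    def snp_ids(self) -> list[str]:
        return self.genotypes.snp_ids


@dataclass
class SimulationParams:
    """Cohort-generator settings.

    ``heritability`` is the fraction of liability variance explained by the
    ``n_causal`` causal SNPs (effects drawn from a standard normal on
    standardised genotypes); the remainder is independent Gaussian noise.
    """

    n_snps: int
    n_individuals: int
    maf_low: float = 0.1
    maf_high: float = 0.5
    n_causal: int = 20
    heritability: float = 0.5
    seed: int = 0
    n_chromosomes: int = 1

    def __post_init__(self) -> None:
        if self.n_snps < 1 or self.n_individuals < 1:
            raise ConfigurationError("n_snps and n_individuals must be positive")
        if not 0.0 < self.maf_low <= self.maf_high <= 0.5:
            raise ConfigurationError("need 0 < maf_low <= maf_high <= 0.5")
        if not 0 <= self.n_causal <= self.n_snps:
            raise ConfigurationError("need 0 <= n_causal <= n_snps")
        if not 0.0 <= self.heritability <= 1.0:
            raise ConfigurationError("heritability must lie in [0, 1]")
        if self.n_chromosomes < 1:
            raise ConfigurationError("n_chromosomes must be >= 1")


@dataclass
class ScenarioSpec:
    """Per-party (case_count, control_count) pairs for a multi-party study."""

    parties: tuple[tuple[int, int], ...]
    name: str = ""

    def __post_init__(self) -> None:
        self.parties = tuple((int(a), int(b)) for a, b in self.parties)
        if not self.parties:
            raise ConfigurationError("a scenario needs at least one party")
        if any(a < 0 or b < 0 for a, b in self.parties):
            raise ConfigurationError("case/control counts must be non-negative")
        if self.total_cases == 0 or self.total_controls == 0:
            raise ConfigurationError("pooled scenario must contain both classes")

    @property
    def total_cases(self) -> int:
        return sum(a for a, _ in self.parties)

    @property
    def total_controls(self) -> int:
        return sum(b for _, b in self.parties)


#: The five two-party heterogeneity scenarios used throughout: balanced,
#: mildly opposed, strongly opposed, both skewed, one balanced / one skewed.
SCENARIO_PRESETS: dict[int, ScenarioSpec] = {
    1: ScenarioSpec(((600, 600), (600, 600)), name="scenario-1"),
    2: ScenarioSpec(((450, 750), (750, 450)), name="scenario-2"),
    3: ScenarioSpec(((300, 900), (900, 300)), name="scenario-3"),
    4: ScenarioSpec(((300, 900), (300, 900)), name="scenario-4"),
    5: ScenarioSpec(((600, 600), (300, 900)), name="scenario-5"),
}


def simulate_genotypes(params: SimulationParams) -> GenotypeMatrix:
    """Draw HWE genotypes with per-SNP MAF ~ Uniform[maf_low, maf_high].

    Each genotype is Binomial(2, f_j), independently across individuals and
    SNPs.  Deterministic given ``params.seed``.
    """
    rng = substream(params.seed, "genotypes")
    mafs = rng.uniform(params.maf_low, params.maf_high, size=params.n_snps)
    values = rng.binomial(2, mafs, size=(params.n_individuals, params.n_snps))
    width = max(4, len(str(params.n_snps)))
    snp_ids = [f"snp{j:0{width}d}" for j in range(params.n_snps)]
    ind_ids = [f"ind{i:06d}" for i in range(params.n_individuals)]
    chrom = None
    if params.n_chromosomes > 1:
        # contiguous blocks of roughly equal size, tagged chr1..chrC
        bounds = np.linspace(0, params.n_snps, params.n_chromosomes + 1).astype(int)
        chrom = []
        for c in range(params.n_chromosomes):
            chrom.extend([f"chr{c + 1}"] * (bounds[c + 1] - bounds[c]))
    return GenotypeMatrix(
        values=values, snp_ids=snp_ids, individual_ids=ind_ids, chrom=chrom, maf=mafs
    )


def simulate_liability_phenotypes(
    genotypes: GenotypeMatrix,
    params: SimulationParams,
    n_cases: Optional[int] = None,
) -> tuple[PhenotypeVector, np.ndarray]:
    """Assign case/control status under a liability-threshold model.

    ``n_causal`` SNPs get effects drawn from a standard normal; the genetic
    liability component is their weighted sum of standardised genotypes,
    rescaled to variance ``heritability``, plus N(0, 1 - heritability) noise.
    The ``n_cases`` individuals with the highest liability become cases
    (default: half the cohort), so exact scenario case counts can be met.

    Returns the phenotype vector and the per-SNP true effect sizes on the
    (rescaled) liability scale -- zero for non-causal SNPs.
    """
    n, m = genotypes.values.shape
    if n_cases is None:
        n_cases = n // 2
    if not 0 < n_cases < n:
        raise ConfigurationError(
            f"requested {n_cases} cases from {n} individuals; need 0 < cases < n"
        )
    rng = substream(params.seed, "phenotypes")
    effects = np.zeros(m)
    h2 = params.heritability
    genetic = np.zeros(n)
    if params.n_causal > 0 and h2 > 0:
        causal = rng.choice(m, size=params.n_causal, replace=False)
        raw = rng.standard_normal(params.n_causal)
        G = genotypes.values[:, causal].astype(float)
        sd = G.std(axis=0)
        sd[sd == 0] = 1.0
        Z = (G - G.mean(axis=0)) / sd
        genetic = Z @ raw
        g_sd = genetic.std()
        if g_sd > 0:
            scale = np.sqrt(h2) / g_sd
            genetic *= scale
            effects[causal] = raw * scale
    liability = genetic + rng.standard_normal(n) * np.sqrt(max(0.0, 1.0 - h2))
    order = np.argsort(-liability, kind="stable")
    labels = np.zeros(n, dtype=np.int8)
    labels[order[:n_cases]] = 1
    return PhenotypeVector(labels=labels), effects


def assemble_scenario(
    genotypes: GenotypeMatrix,
    phenotypes: PhenotypeVector,
    scenario: ScenarioSpec,
    seed: int = 0,
) -> list[PartyDataset]:
    """Partition a pooled cohort into party datasets with exact class counts.

    Individuals are sampled without replacement from the pooled case and
    control pools, so no individual appears in two parties.  Deterministic
    given ``seed``.
    """
    labels = phenotypes.labels
    rng = substream(seed, "scenario")
    case_pool = np.flatnonzero(labels == 1)
    control_pool = np.flatnonzero(labels == 0)
    need_cases, need_controls = scenario.total_cases, scenario.total_controls
    if need_cases > case_pool.size:
        raise ScenarioError(
            f"scenario needs {need_cases} cases but only {case_pool.size} available"
        )
    if need_controls > control_pool.size:
        raise ScenarioError(
            f"scenario needs {need_controls} controls but only "
            f"{control_pool.size} available"
        )
    case_pool = rng.permutation(case_pool)
    control_pool = rng.permutation(control_pool)
    parties = []
    ci = ki = 0
    for p, (n_case, n_control) in enumerate(scenario.parties):
        take = np.concatenate(
            [case_pool[ki : ki + n_case], control_pool[ci : ci + n_control]]
        )
        ki += n_case
        ci += n_control
        party_id = chr(ord("A") + p) if p < 26 else f"party{p}"
        parties.append(
            PartyDataset(
                party_id=party_id,
                genotypes=genotypes.take_individuals(take),
                phenotypes=PhenotypeVector(labels=labels[take]),
            )
        )
    return parties


def pool_parties(parties: Sequence[PartyDataset]) -> tuple[np.ndarray, np.ndarray]:
    """Row-concatenate party genotypes/phenotypes (columns aligned to the first)."""
    first = parties[0].snp_ids
    blocks, ys = [], []
    for p in parties:
        g = p.genotypes if p.snp_ids == first else p.genotypes.take_snps(first)
        blocks.append(g.values)
        ys.append(p.phenotypes.labels)
    return np.vstack(blocks), np.concatenate(ys)
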