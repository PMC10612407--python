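"""Genotype file formats and experiment configuration.

Three plain-text dialects are supported and round-trip with each other:

* ``tsv`` -- header row ``individual_id  phenotype  <snp ids...>``, one
  individual per row, additive minor-allele dosages.
* ``plink_raw`` -- PLINK ``--recode A``-style: whitespace-delimited with
  ``FID IID PAT MAT SEX PHENOTYPE`` then one ``<snp>_<allele>`` dosage column
  per SNP; phenotype coded 1=control / 2=case on disk.
* ``vcf`` -- minimal VCF v4.2, biallelic GT-only records with ALT as the
  minor allele.  VCF carries no phenotype, so a sidecar ``<path>.pheno.tsv``
  (individual_id, phenotype) is written and read alongside.

Genomic coordinates are never interpreted: single-SNP tests need no
positions, and chromosome tags are opaque batch keys.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from tdsgwas.errors import ConfigurationError, FormatError
from tdsgwas.federation import ProtocolConfig
from tdsgwas.synthetic_cohorts import (
    GenotypeMatrix,
    PartyDataset,
    PhenotypeVector,
    SCENARIO_PRESETS,
    ScenarioSpec,
    SimulationParams,
)

__all__ = [
    "read_genotypes",
    "write_genotypes",
    "ExperimentConfig",
    "load_config",
    "write_manifest",
]

_FORMATS = ("tsv", "plink_raw", "vcf")


# --------------------------------------------------------------------------
# readers / writers
# --------------------------------------------------------------------------

def write_genotypes(dataset: PartyDataset, path, format: str = "tsv") -> None:
    path = Path(path)
    if format == "tsv":
        _write_tsv(dataset, path)
    elif format == "plink_raw":
        _write_raw(dataset, path)
    elif format == "vcf":
        _write_vcf(dataset, path)
    else:
        raise FormatError(f"unknown format {format!r}; expected one of {_FORMATS}")


def read_genotypes(path, format: str = "tsv", party_id: Optional[str] = None) -> PartyDataset:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if format == "tsv":
        ds = _read_tsv(path)
    elif format == "plink_raw":
        ds = _read_raw(path)
    elif format == "vcf":
        ds = _read_vcf(path)
    else:
        raise FormatError(f"unknown format {format!r}; expected one of {_FORMATS}")
    if party_id is not None:
        ds = PartyDataset(party_id, ds.genotypes, ds.phenotypes)
    return ds


def _write_tsv(dataset: PartyDataset, path: Path) -> None:
    df = pd.DataFrame(
        dataset.genotypes.values,
        columns=dataset.genotypes.snp_ids,
    )
    df.insert(0, "phenotype", dataset.phenotypes.labels)
    df.insert(0, "individual_id", dataset.genotypes.individual_ids)
    df.to_csv(path, sep="\t", index=False)


def _read_tsv(path: Path) -> PartyDataset:
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise FormatError(f"{path}: not parseable as TSV ({exc})") from exc
    if df.columns[:2].tolist() != ["individual_id", "phenotype"]:
        raise FormatError(
            f"{path}: line 1: header must start 'individual_id\\tphenotype'"
        )
    snp_cols = df.columns[2:].tolist()
    values = df[snp_cols].to_numpy()
    if np.isnan(values.astype(float)).any():
        raise FormatError(f"{path}: missing genotypes are not supported")
    geno = GenotypeMatrix(
        values=values.astype(int),
        snp_ids=snp_cols,
        individual_ids=df["individual_id"].astype(str).tolist(),
    )
    pheno = PhenotypeVector(labels=df["phenotype"].to_numpy())
    return PartyDataset(path.stem, geno, pheno)


_RAW_META = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


def _write_raw(dataset: PartyDataset, path: Path) -> None:
    df = pd.DataFrame(
        dataset.genotypes.values,
        columns=[f"{s}_A" for s in dataset.genotypes.snp_ids],
    )
    ids = dataset.genotypes.individual_ids
    meta = pd.DataFrame(
        {
            "FID": ids,
            "IID": ids,
            "PAT": 0,
            "MAT": 0,
            "SEX": 0,
            "PHENOTYPE": dataset.phenotypes.labels + 1,  # 1=control, 2=case
        }
    )
    pd.concat([meta, df], axis=1).to_csv(path, sep=" ", index=False)


def _read_raw(path: Path) -> PartyDataset:
    try:
        df = pd.read_csv(path, sep=r"\s+")
    except Exception as exc:
        raise FormatError(f"{path}: not parseable as PLINK raw ({exc})") from exc
    if df.columns[:6].tolist() != _RAW_META:
        raise FormatError(
            f"{path}: line 1: header must start {' '.join(_RAW_META)}"
        )
    snp_cols = df.columns[6:].tolist()
    # strip the trailing _<allele> suffix PLINK appends to each SNP column
    snp_ids = [c.rsplit("_", 1)[0] if "_" in c else c for c in snp_cols]
    values = df[snp_cols].to_numpy(dtype=float)
    if np.isnan(values).any():
        raise FormatError(f"{path}: missing genotypes are not supported")
    pheno_raw = df["PHENOTYPE"].to_numpy()
    if not np.isin(pheno_raw, (1, 2)).all():
        raise FormatError(f"{path}: PHENOTYPE must be coded 1 (control) / 2 (case)")
    geno = GenotypeMatrix(
        values=values.astype(int),
        snp_ids=snp_ids,
        individual_ids=df["IID"].astype(str).tolist(),
    )
    return PartyDataset(path.stem, geno, PhenotypeVector(labels=pheno_raw - 1))


_GT_CODE = {0: "0/0", 1: "0/1", 2: "1/1"}


def _pheno_sidecar(path: Path) -> Path:
    return path.with_name(path.name + ".pheno.tsv")


def _write_vcf(dataset: PartyDataset, path: Path) -> None:
    g = dataset.genotypes
    chroms = g.chrom if g.chrom is not None else ["1"] * g.n_snps
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in dict.fromkeys(chroms):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.individual_ids)
            + "\n"
        )
        for j, snp in enumerate(g.snp_ids):
            gts = "\t".join(_GT_CODE[int(v)] for v in g.values[:, j])
            fh.write(f"{chroms[j]}\t{j + 1}\t{snp}\tA\tG\t.\t.\t.\tGT\t{gts}\n")
    pd.DataFrame(
        {"individual_id": g.individual_ids, "phenotype": dataset.phenotypes.labels}
    ).to_csv(_pheno_sidecar(path), sep="\t", index=False)


def _read_vcf(path: Path) -> PartyDataset:
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise FormatError("reading VCF requires the cyvcf2 package") from exc
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    snp_ids: list[str] = []
    chroms: list[str] = []
    columns: list[np.ndarray] = []
    for k, record in enumerate(vcf):
        if len(record.ALT) != 1:
            warnings.warn(
                f"{path}: skipping non-biallelic record {record.ID or k}",
                stacklevel=2,
            )
            continue
        dosage = np.array(
            [a + b for a, b, *_ in record.genotypes], dtype=float
        )
        if (np.array(record.genotypes)[:, :2] < 0).any():
            raise FormatError(
                f"{path}: missing genotype at record {record.ID or k}"
            )
        # minor-allele orientation: flip when ALT is the sample-major allele
        if dosage.mean() / 2.0 > 0.5:
            dosage = 2.0 - dosage
        columns.append(dosage.astype(int))
        snp_ids.append(record.ID or f"{record.CHROM}:{record.POS}")
        chroms.append(str(record.CHROM))
    if not columns:
        raise FormatError(f"{path}: no usable biallelic records")
    sidecar = _pheno_sidecar(path)
    if not sidecar.exists():
        raise FormatError(
            f"{path}: phenotype sidecar {sidecar.name} not found "
            "(VCF carries no phenotype)"
        )
    ph = pd.read_csv(sidecar, sep="\t")
    ph = ph.set_index("individual_id").loc[samples, "phenotype"]
    geno = GenotypeMatrix(
        values=np.column_stack(columns),
        snp_ids=snp_ids,
        individual_ids=samples,
        chrom=chroms,
    )
    return PartyDataset(path.stem, geno, PhenotypeVector(labels=ph.to_numpy()))


# --------------------------------------------------------------------------
# experiment configuration
# --------------------------------------------------------------------------

class SimulationSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_snps: int = 2000
    n_individuals: int = 2400
    maf_low: float = 0.1
    maf_high: float = 0.5
    n_causal: int = 20
    heritability: float = 0.5
    n_chromosomes: int = 1

    def to_params(self, seed: int) -> SimulationParams:
        return SimulationParams(seed=seed, **self.model_dump())


class ProtocolSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    K: int = 500
    mu_phase1: float = 0.3
    mu_phase2: float = 0.3
    m: int = 300
    max_iterations: int = 9
    intercept: bool = True
    freeze_stable_batches: bool = False

    def to_config(self, master_seed: int) -> ProtocolConfig:
        return ProtocolConfig(master_seed=master_seed, **self.model_dump())


class ExperimentConfig(BaseModel):
    """One reproducible experiment: scenario x simulation x protocol."""

    model_config = ConfigDict(extra="forbid")
    scenario: int | list[list[int]] = 1
    simulation: SimulationSettings = Field(default_factory=SimulationSettings)
    protocol: ProtocolSettings = Field(default_factory=ProtocolSettings)
    truth_threshold: float = 0.005
    n_replicates: int = 5
    seed: int = 0
    output_dir: str = "results"

    def scenario_spec(self) -> ScenarioSpec:
        if isinstance(self.scenario, int):
            try:
                return SCENARIO_PRESETS[self.scenario]
            except KeyError:
                raise ConfigurationError(
                    f"unknown scenario preset {self.scenario}; presets are "
                    f"{sorted(SCENARIO_PRESETS)}"
                ) from None
        return ScenarioSpec(
            tuple(tuple(p) for p in self.scenario), name="custom"
        )


def load_config(path) -> ExperimentConfig:
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text()) or {}
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"{path}: invalid YAML ({exc})") from exc
    try:
        return ExperimentConfig.model_validate(raw)
    except Exception as exc:
        raise ConfigurationError(f"{path}: {exc}") from exc


def write_manifest(out_dir, config: ExperimentConfig, extra: Optional[dict] = None) -> Path:
    """JSON manifest (config, its hash, seed, package version) for re-runs."""
    from tdsgwas import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = config.model_dump()
    manifest = {
        "config": payload,
        "config_sha256": hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest(),
        "seed": config.seed,
        "tdsgwas_version": __version__,
    }
    if extra:
        manifest.update(extra)
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path
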