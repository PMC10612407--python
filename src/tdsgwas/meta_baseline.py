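"""Random-effects meta-analysis baseline.

The conventional privacy-light alternative to pooling data: each party
computes per-SNP summary statistics locally (a logistic log-odds estimate
with its variance, or a Cochran-Armitage trend z treated as a unit-variance
effect) and only these summaries are combined.  Combination uses the
DerSimonian-Laird random-effects estimator: Cochran's Q over inverse-variance
weights gives the between-study variance tau^2 = max(0, (Q - df) / C), and
the combined effect is the 1/(v_i + tau^2)-weighted mean with a two-sided
normal p-value.  When tau^2 = 0 this reduces exactly to the fixed-effects
inverse-variance combination.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from tdsgwas.assoc_tests import TrendTable, catt_additive, logistic_wald_scan
from tdsgwas.errors import DegenerateOutcomeError
from tdsgwas.synthetic_cohorts import PartyDataset

__all__ = [
    "StudyEffect",
    "MetaResult",
    "per_study_effects",
    "random_effects_combine",
    "meta_scan",
    "meta_labels",
]


@dataclass
class StudyEffect:
    """One study's per-SNP summary statistic: effect and its variance.

    An inestimable effect (separation, constant genotype) carries infinite
    variance, i.e. zero weight in the combination.
    """

    snp_id: str
    study_id: str
    effect: float
    variance: float

    def __post_init__(self) -> None:
        if not self.variance > 0:
            raise ValueError(
                f"{self.snp_id}/{self.study_id}: variance must be positive"
            )


@dataclass
class MetaResult:
    snp_id: str
    effect: float
    variance: float
    tau2: float
    p_value: float
    n_studies: int


def per_study_effects(
    party: PartyDataset, method: str = "logistic"
) -> list[StudyEffect]:
    """Per-SNP summary effects from one party's local data.

    ``logistic``: (beta, se^2) from the local Wald fit.  ``catt``: the trend z
    as a signed effect with unit variance.  A single-class party cannot
    produce summaries and raises ``DegenerateOutcomeError``.
    """
    y = party.phenotypes.labels
    if y.min() == y.max():
        raise DegenerateOutcomeError(
            f"party {party.party_id!r} holds a single phenotype class"
        )
    out = []
    if method == "logistic":
        res = logistic_wald_scan(party.genotypes.values, y)
        for j, snp in enumerate(party.snp_ids):
            if res.converged[j]:
                eff, var = float(res.beta[j]), float(res.se[j]) ** 2
            else:
                eff, var = 0.0, np.inf
            out.append(StudyEffect(snp, party.party_id, eff, var))
    elif method == "catt":
        for j, snp in enumerate(party.snp_ids):
            table = TrendTable.from_column(party.genotypes.values[:, j], y)
            try:
                z, _ = catt_additive(table)
                eff, var = z, 1.0
            except Exception:
                eff, var = 0.0, np.inf
            out.append(StudyEffect(snp, party.party_id, eff, var))
    else:
        raise ValueError(f"unknown method {method!r}")
    return out


def random_effects_combine(effects: Sequence[StudyEffect]) -> MetaResult:
    """DerSimonian-Laird combination of one SNP's effects across studies."""
    effects = list(effects)
    if len(effects) < 2:
        raise ValueError("random-effects combination needs >= 2 studies")
    snp = effects[0].snp_id
    if any(e.snp_id != snp for e in effects):
        raise ValueError("effects belong to different SNPs")
    e = np.array([s.effect for s in effects])
    v = np.array([s.variance for s in effects])
    w = np.where(np.isfinite(v), 1.0 / v, 0.0)
    wsum = w.sum()
    if wsum == 0:
        return MetaResult(snp, np.nan, np.nan, np.nan, np.nan, len(effects))
    mean_fe = (w * e).sum() / wsum
    q = (w * (e - mean_fe) ** 2).sum()
    df = (w > 0).sum() - 1
    c = wsum - (w * w).sum() / wsum
    tau2 = max(0.0, (q - df) / c) if c > 0 else 0.0
    w_star = np.where(np.isfinite(v), 1.0 / (v + tau2), 0.0)
    combined = (w_star * e).sum() / w_star.sum()
    var = 1.0 / w_star.sum()
    z = combined / np.sqrt(var)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return MetaResult(snp, float(combined), float(var), float(tau2), p, len(effects))


def meta_scan(
    parties: Sequence[PartyDataset], method: str = "logistic"
) -> list[MetaResult]:
    """Random-effects meta-analysis of every SNP across the parties."""
    per_study = [per_study_effects(p, method=method) for p in parties]
    snp_ids = parties[0].snp_ids
    by_snp: dict[str, list[StudyEffect]] = {s: [] for s in snp_ids}
    for study in per_study:
        for eff in study:
            by_snp[eff.snp_id].append(eff)
    return [random_effects_combine(by_snp[s]) for s in snp_ids]


def meta_labels(
    parties: Sequence[PartyDataset],
    threshold: float,
    method: str = "catt",
) -> dict[str, int]:
    """Binary significance labels from the meta-analysis (p < threshold)."""
    return {
        r.snp_id: int(np.isfinite(r.p_value) and r.p_value < threshold)
        for r in meta_scan(parties, method=method)
    }


def effects_to_frame(effects: Sequence[StudyEffect]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "snp_id": [e.snp_id for e in effects],
            "study_id": [e.study_id for e in effects],
            "effect": [e.effect for e in effects],
            "variance": [e.variance for e in effects],
        }
    )


def meta_to_frame(results: Sequence[MetaResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "snp_id": [r.snp_id for r in results],
            "effect": [r.effect for r in results],
            "variance": [r.variance for r in results],
            "tau2": [r.tau2 for r in results],
            "p_value": [r.p_value for r in results],
            "n_studies": [r.n_studies for r in results],
        }
    )
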