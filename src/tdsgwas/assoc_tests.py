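"""Single-SNP association statistics.

The workhorse is a per-SNP logistic regression of case status on minor-allele
count, P(y=1 | x) = sigmoid(a + b*x), tested with the Wald statistic
(b / se(b))^2 against chi-square(1).  All SNPs of a scan are fitted
simultaneously by a batch-vectorised Newton (IRLS) solver: each SNP is a
two-parameter problem whose score and 2x2 Hessian are accumulated by matrix
reductions across SNPs, so a full scan of thousands of SNPs costs a handful
of dense passes over the genotype matrix.

The intercept is included by default: the collaborating parties' case:control
ratios differ by design, and an intercept-free fit would confound that
imbalance with the genetic effect.  An intercept-free fit (the literal
single-parameter model) is available via ``intercept=False``.

Also provided: the additive Cochran-Armitage trend test on 2x3 tables and the
Bonferroni threshold helper.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from tdsgwas.errors import DegenerateOutcomeError, NoVariationError
from tdsgwas.synthetic_cohorts import PartyDataset, PhenotypeVector, pool_parties

__all__ = [
    "AssocResult",
    "ScanResult",
    "TrendTable",
    "logistic_wald_scan",
    "fit_logistic_wald",
    "run_single_snp_scan",
    "catt_additive",
    "bonferroni_threshold",
    "results_to_frame",
]

_MAX_ITER = 25
_TOL = 1e-8
_ETA_CLIP = 30.0


@dataclass
class AssocResult:
    """One SNP's logistic Wald fit.

    When ``converged`` is False the estimate is unreliable (typically quasi-
    complete separation or a constant column); ``p_value`` is NaN and callers
    must treat the SNP as undetermined (downstream protocol code counts it as
    insignificant, which is conservative for false positives).
    """

    snp_id: str
    beta: float
    se: float
    wald_stat: float
    p_value: float
    converged: bool


@dataclass
class ScanResult:
    """Vectorised scan output, one entry per genotype column."""

    beta: np.ndarray
    se: np.ndarray
    wald: np.ndarray
    p_value: np.ndarray
    converged: np.ndarray
    n_iter: int

    @property
    def n_snps(self) -> int:
        return self.beta.shape[0]


def logistic_wald_scan(
    X: np.ndarray,
    y: np.ndarray,
    intercept: bool = True,
    max_iter: int = _MAX_ITER,
    tol: float = _TOL,
) -> ScanResult:
    """Fit one logistic regression per column of ``X`` and Wald-test the slope.

    ``X`` is (individuals x SNPs) with values {0,1,2}; ``y`` is the 0/1
    phenotype.  Newton/IRLS, convergence when the largest absolute coefficient
    update falls below ``tol``.  Columns that fail to converge in ``max_iter``
    steps (separation) or have no variation are flagged ``converged=False``
    with NaN p-values; the scan never raises for individual columns.

    Raises ``DegenerateOutcomeError`` if ``y`` contains a single class.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=np.float64)
    n, m = X.shape
    if y.shape != (n,):
        raise ValueError(f"phenotype length {y.shape} does not match {n} rows")
    if y.min() == y.max():
        raise DegenerateOutcomeError("phenotype vector contains a single class")

    varying = X.min(axis=0) != X.max(axis=0)
    beta = np.zeros(m)
    alpha = np.full(m, _logit(y.mean()) if intercept else 0.0)
    active = varying.copy()
    done_iter = 0
    for it in range(max_iter):
        if not active.any():
            break
        done_iter = it + 1
        Xa = X[:, active]
        eta = np.clip(alpha[active] + Xa * beta[active], -_ETA_CLIP, _ETA_CLIP)
        p = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(p * (1.0 - p), 1e-12, None)
        r = y[:, None] - p
        g1 = (r * Xa).sum(axis=0)
        h11 = (w * Xa * Xa).sum(axis=0)
        if intercept:
            g0 = r.sum(axis=0)
            h00 = w.sum(axis=0)
            h01 = (w * Xa).sum(axis=0)
            det = h00 * h11 - h01 * h01
            with np.errstate(divide="ignore", invalid="ignore"):
                da = (h11 * g0 - h01 * g1) / det
                db = (h00 * g1 - h01 * g0) / det
        else:
            with np.errstate(divide="ignore", invalid="ignore"):
                da = np.zeros_like(g1)
                db = g1 / h11
        bad = ~np.isfinite(da) | ~np.isfinite(db)
        da[bad] = 0.0
        db[bad] = 0.0
        alpha[active] += da
        beta[active] += db
        step = np.maximum(np.abs(da), np.abs(db))
        settled = (step < tol) & ~bad
        idx = np.flatnonzero(active)
        active[idx[settled]] = False
        active[idx[bad]] = False
        if bad.any():
            varying_fail = idx[bad]
            varying[varying_fail] = False  # numerically degenerate: flag out

    converged = varying & ~active
    # standard errors from the final observed information
    se = np.full(m, np.nan)
    if converged.any():
        Xc = X[:, converged]
        eta = np.clip(alpha[converged] + Xc * beta[converged], -_ETA_CLIP, _ETA_CLIP)
        p = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(p * (1.0 - p), 1e-12, None)
        h11 = (w * Xc * Xc).sum(axis=0)
        if intercept:
            h00 = w.sum(axis=0)
            h01 = (w * Xc).sum(axis=0)
            det = h00 * h11 - h01 * h01
            with np.errstate(divide="ignore", invalid="ignore"):
                var = h00 / det
        else:
            with np.errstate(divide="ignore", invalid="ignore"):
                var = 1.0 / h11
        var = np.where(np.isfinite(var) & (var > 0), var, np.nan)
        se[converged] = np.sqrt(var)
    converged = converged & np.isfinite(se)

    wald = np.full(m, np.nan)
    pvals = np.full(m, np.nan)
    ok = converged
    with np.errstate(invalid="ignore", divide="ignore"):
        wald[ok] = (beta[ok] / se[ok]) ** 2
    pvals[ok] = stats.chi2.sf(wald[ok], df=1)
    beta_out = np.where(converged, beta, np.nan)
    return ScanResult(
        beta=beta_out,
        se=se,
        wald=wald,
        p_value=pvals,
        converged=converged,
        n_iter=done_iter,
    )


def _logit(p: float) -> float:
    p = min(max(p, 1e-12), 1 - 1e-12)
    return float(np.log(p / (1 - p)))


def fit_logistic_wald(
    genotype_column: Sequence[int],
    phenotypes: Union[PhenotypeVector, Sequence[int]],
    intercept: bool = True,
    snp_id: str = "",
) -> AssocResult:
    """Single-SNP logistic Wald test.

    Raises ``NoVariationError`` for a constant genotype column and
    ``DegenerateOutcomeError`` for a single-class phenotype.  Separation is
    reported through ``converged=False`` rather than an exception.
    """
    x = np.asarray(genotype_column, dtype=float)
    y = phenotypes.labels if isinstance(phenotypes, PhenotypeVector) else phenotypes
    y = np.asarray(y, dtype=float)
    if x.min() == x.max():
        raise NoVariationError("genotype column is constant")
    res = logistic_wald_scan(x[:, None], y, intercept=intercept)
    return AssocResult(
        snp_id=snp_id,
        beta=float(res.beta[0]),
        se=float(res.se[0]),
        wald_stat=float(res.wald[0]),
        p_value=float(res.p_value[0]),
        converged=bool(res.converged[0]),
    )


def run_single_snp_scan(
    dataset: Union[PartyDataset, Sequence[PartyDataset]],
    intercept: bool = True,
) -> list[AssocResult]:
    """Independent per-SNP logistic Wald tests, in input column order.

    Accepts one party or a sequence of parties (pooled by row concatenation
    with columns aligned to the first party).  Per-SNP failures (constant
    columns, separation) surface as non-converged results; a single-class
    pooled phenotype raises ``DegenerateOutcomeError``.
    """
    if isinstance(dataset, PartyDataset):
        X = dataset.genotypes.values
        y = dataset.phenotypes.labels
        snp_ids = dataset.snp_ids
    else:
        parties = list(dataset)
        X, y = pool_parties(parties)
        snp_ids = parties[0].snp_ids
    res = logistic_wald_scan(X, y, intercept=intercept)
    return [
        AssocResult(
            snp_id=snp_ids[j],
            beta=float(res.beta[j]),
            se=float(res.se[j]),
            wald_stat=float(res.wald[j]),
            p_value=float(res.p_value[j]),
            converged=bool(res.converged[j]),
        )
        for j in range(res.n_snps)
    ]


@dataclass
class TrendTable:
    """2x3 case/control counts at genotype 0/1/2 with additive scores."""

    cases: tuple[int, int, int]
    controls: tuple[int, int, int]
    scores: tuple[float, float, float] = (0.0, 1.0, 2.0)

    def __post_init__(self) -> None:
        self.cases = tuple(int(c) for c in self.cases)
        self.controls = tuple(int(c) for c in self.controls)
        if any(c < 0 for c in self.cases + self.controls):
            raise ValueError("trend-table counts must be non-negative")

    @classmethod
    def from_column(
        cls, genotype_column: Sequence[int], labels: Sequence[int]
    ) -> "TrendTable":
        x = np.asarray(genotype_column)
        y = np.asarray(labels)
        cases = tuple(int(((x == g) & (y == 1)).sum()) for g in (0, 1, 2))
        controls = tuple(int(((x == g) & (y == 0)).sum()) for g in (0, 1, 2))
        return cls(cases=cases, controls=controls)


def catt_additive(table: TrendTable) -> tuple[float, float]:
    """Cochran-Armitage trend test with additive scores.

    z = U / sqrt(Var U) with U the score-weighted excess of cases over their
    expectation under independence and the usual score-test variance
    R*C*(N*sum(s^2 n) - (sum(s n))^2) / N^3.  Two-sided normal p-value.
    Invariant under affine rescaling of the scores.
    """
    r = np.asarray(table.cases, dtype=float)
    c = np.asarray(table.controls, dtype=float)
    s = np.asarray(table.scores, dtype=float)
    n = r + c
    R, C, N = r.sum(), c.sum(), (r + c).sum()
    if R == 0 or C == 0:
        raise DegenerateOutcomeError("trend table needs both cases and controls")
    score_var = N * (s * s * n).sum() - (s * n).sum() ** 2
    if score_var <= 0:
        raise NoVariationError("all individuals share one genotype category")
    u = (s * r).sum() - R / N * (s * n).sum()
    var_u = R * C * score_var / N**3
    z = float(u / np.sqrt(var_u))
    p = float(2.0 * stats.norm.sf(abs(z)))
    return z, p


def bonferroni_threshold(alpha: float, n: int) -> float:
    """Family-wise threshold alpha / n for ``n`` simultaneous tests."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    return alpha / n


def results_to_frame(results: Sequence[AssocResult]) -> pd.DataFrame:
    """Tabulate scan results (TSV-ready: snp_id, beta, se, wald, p, converged)."""
    return pd.DataFrame(
        {
            "snp_id": [r.snp_id for r in results],
            "beta": [r.beta for r in results],
            "se": [r.se for r in results],
            "wald_stat": [r.wald_stat for r in results],
            "p_value": [r.p_value for r in results],
            "converged": [r.converged for r in results],
        }
    )
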