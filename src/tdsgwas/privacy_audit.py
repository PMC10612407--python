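"""Privacy surface of a protocol run.

Two quantities are audited.  First, cumulative *exposure*: the fraction of a
party's individuals whose (de-identified) data has reached the server after T
iterations of uniform sampling -- the price of the iterative design.  Second,
the strength of a simplified honest-but-curious *unshuffling adversary*: a
server that knows candidate reference minor-allele frequencies and tries to
re-identify the shuffled columns of a share by matching estimated to
reference MAFs by rank.  This is a deliberate lower bound on attack power
(real attackers can additionally exploit linkage disequilibrium and public
panels); the audit reports metrics without pass/fail thresholds.

Party-private permutations and sampled row sets are never read directly from
protocol state by the adversary code: the audit harness receives them
explicitly as the evaluation ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from tdsgwas._rng import substream

__all__ = [
    "ExposureLog",
    "audit_exposure",
    "maf_rank_unshuffle",
    "unshuffle_accuracy",
    "adversary_experiment",
]


@dataclass
class ExposureLog:
    """Per-party, per-iteration record of which individuals were sampled.

    ``samples[party]`` is a list (one entry per iteration) of arrays of
    sampled row indices; ``column_seeds`` keeps per-iteration batch seed
    fingerprints for the audit trail.
    """

    party_sizes: dict[str, int]
    samples: dict[str, list[np.ndarray]] = field(default_factory=dict)
    column_seeds: list[tuple[int, ...]] = field(default_factory=list)

    def record(self, party_id: str, indices: np.ndarray) -> None:
        if party_id not in self.party_sizes:
            raise KeyError(f"unknown party {party_id!r}")
        idx = np.asarray(indices, dtype=int)
        n = self.party_sizes[party_id]
        if idx.min(initial=0) < 0 or idx.max(initial=-1) >= n:
            raise ValueError(f"indices out of range for party of size {n}")
        self.samples.setdefault(party_id, []).append(idx)

    @property
    def n_iterations(self) -> int:
        return max((len(v) for v in self.samples.values()), default=0)


def audit_exposure(log: ExposureLog) -> dict[str, np.ndarray]:
    """Cumulative exposure curves: fraction of each party seen by the server.

    Entry T-1 of a party's curve is |union of samples over iterations 1..T|
    divided by the party size; the curve is non-decreasing by construction.
    """
    if not log.samples:
        raise ValueError("empty exposure log")
    curves = {}
    for party, draws in log.samples.items():
        n = log.party_sizes[party]
        seen: set[int] = set()
        curve = []
        for idx in draws:
            seen.update(int(i) for i in idx)
            curve.append(len(seen) / n)
        curves[party] = np.array(curve)
    return curves


def maf_rank_unshuffle(
    share_genotypes: np.ndarray,
    candidate_mafs: Sequence[float],
) -> np.ndarray:
    """Greedy MAF-rank matching of shuffled columns to candidate SNPs.

    Columns are ordered by their estimated allele frequency (column mean / 2)
    and greedily matched, in that order, to the unused candidate with the
    nearest reference frequency (ties broken by candidate order).  Returns
    ``guess`` with ``guess[k]`` = candidate index claimed for share column k.
    """
    G = np.asarray(share_genotypes, dtype=float)
    ref = np.asarray(candidate_mafs, dtype=float)
    m = G.shape[1]
    if ref.shape[0] < m:
        raise ValueError(
            f"{ref.shape[0]} candidates for {m} columns; need at least as many"
        )
    est = G.mean(axis=0) / 2.0
    order = np.argsort(est, kind="stable")
    available = np.ones(ref.shape[0], dtype=bool)
    guess = np.empty(m, dtype=int)
    for k in order:
        d = np.abs(ref - est[k])
        d[~available] = np.inf
        best = int(np.argmin(d))  # np.argmin takes the first minimum: ties
        available[best] = False   # break toward the lower candidate index
        guess[k] = best
    return guess


def unshuffle_accuracy(guess: np.ndarray, truth: np.ndarray) -> float:
    """Fraction of share columns whose claimed SNP matches the true mapping."""
    guess = np.asarray(guess)
    truth = np.asarray(truth)
    if guess.shape != truth.shape:
        raise ValueError("guess and truth mappings differ in length")
    return float((guess == truth).mean())


def adversary_experiment(
    n_snps: int,
    K: int,
    maf_low: float = 0.1,
    maf_high: float = 0.5,
    mafs: Optional[np.ndarray] = None,
    n_decoys: int = 0,
    seed: int = 0,
) -> float:
    """End-to-end unshuffling trial: simulate one share, attack it, score it.

    Draws HWE genotypes for ``K`` sampled individuals at ``n_snps`` SNPs with
    reference MAFs either supplied or uniform on [maf_low, maf_high], shuffles
    columns with a fresh permutation, and runs the MAF-rank adversary with the
    *true* reference frequencies as candidates (the favourable case for the
    attacker).  ``n_decoys`` appends synthetic decoy columns drawn from the
    same reference band before shuffling; accuracy is then scored on the real
    columns only.  Returns the re-identification accuracy.
    """
    rng = substream(seed, "adversary")
    if mafs is None:
        mafs = rng.uniform(maf_low, maf_high, size=n_snps)
    mafs = np.asarray(mafs, dtype=float)
    if n_decoys:
        decoy_mafs = rng.uniform(maf_low, maf_high, size=n_decoys)
        mafs = np.concatenate([mafs, decoy_mafs])
    G = rng.binomial(2, mafs, size=(K, mafs.shape[0]))
    m_total = mafs.shape[0]
    perm = rng.permutation(m_total)  # column k of the share holds SNP perm[k]
    share = G[:, perm]
    guess = maf_rank_unshuffle(share, mafs)
    real = perm < n_snps  # decoy columns do not count toward the attacker
    return unshuffle_accuracy(guess[real], perm[real])
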