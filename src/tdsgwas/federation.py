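"""The two-step dynamic-sampling federation protocol.

Phase 1 (local screening): each party scans its own data with the logistic
Wald test and nominates SNPs whose local p-value exceeds a lenient threshold
``mu_phase1``; SNPs nominated by *every* party are pruned from the study and
carry a final label of 0.

Phase 2 (dynamic sampling): at each iteration the parties agree on a
partition of the surviving SNPs into batches of at most ``m`` and a common
column-shuffle seed per batch; each party samples ``K`` individuals uniformly
at random (deliberately ignoring case/control balance), shuffles columns with
the common seed and rows with a private permutation, strips all identifiers,
and sends the resulting block to the server.  The server pools the blocks,
returns per-column logistic Wald p-values, and each party inverts the column
shuffle and labels SNP i significant at iteration T iff p <= mu_phase2.
Labels are aggregated across iterations by majority vote with ties resolved
to insignificant; the protocol halts when the majority labels stop changing
or after ``max_iterations``.

All actors are in-process objects honouring the information-flow contract:
the server-side code receives only :class:`AnonymizedShare` blocks, which
contain no SNP or individual identifiers.  Networking, encryption and private
set intersection are out of scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from tdsgwas._rng import subseed, substream
from tdsgwas.assoc_tests import logistic_wald_scan
from tdsgwas.errors import ConfigurationError, ProtocolError
from tdsgwas.privacy_audit import ExposureLog
from tdsgwas.synthetic_cohorts import PartyDataset

logger = logging.getLogger(__name__)

__all__ = [
    "ProtocolConfig",
    "IterationPlan",
    "AnonymizedShare",
    "SampleRecord",
    "LabelHistory",
    "ProtocolResult",
    "local_screen",
    "intersect_insignificant",
    "prune",
    "plan_iteration",
    "sample_and_shuffle",
    "server_compute",
    "unshuffle_and_label",
    "majority_label",
    "check_stop",
    "run_protocol",
]


@dataclass
class ProtocolConfig:
    """Protocol parameters.

    ``mu_phase1`` screens locally (lenient by design: a Bonferroni-level
    threshold here would discard true signals); ``mu_phase2`` is the
    per-iteration labelling threshold and may differ from phase 1.  ``K`` is
    the number of individuals each party samples per iteration, ``m`` the
    maximum SNPs per batch.
    """

    K: int
    mu_phase1: float = 0.3
    mu_phase2: float = 0.3
    m: int = 300
    max_iterations: int = 9
    master_seed: int = 0
    intercept: bool = True
    freeze_stable_batches: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.mu_phase1 <= 1 or not 0 < self.mu_phase2 <= 1:
            raise ConfigurationError("thresholds must lie in (0, 1]")
        if self.K < 1 or self.m < 1 or self.max_iterations < 1:
            raise ConfigurationError("K, m and max_iterations must be >= 1")


@dataclass
class IterationPlan:
    """Agreed batching for one iteration: disjoint SNP batches covering the
    remaining set, one fresh column seed per batch, and the sample size K."""

    iteration: int
    batches: list[tuple[str, ...]]
    column_seeds: list[int]
    K: int

    def __post_init__(self) -> None:
        flat = [s for b in self.batches for s in b]
        if len(set(flat)) != len(flat):
            raise ProtocolError("iteration batches overlap")
        if len(self.column_seeds) != len(self.batches):
            raise ProtocolError("need exactly one column seed per batch")


@dataclass
class AnonymizedShare:
    """De-identified block sent to the server.

    ``data`` is (K x (m+1)): column-shuffled genotypes for one batch with the
    phenotype as the last column, rows in a party-private shuffled order.  No
    identifier fields exist on this object by construction.
    """

    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2 or self.data.shape[1] < 2:
            raise ProtocolError("share must be 2-D with genotypes + phenotype")
        if not np.isin(self.data[:, :-1], (0, 1, 2)).all():
            raise ProtocolError("share genotypes must be 0/1/2")
        if not np.isin(self.data[:, -1], (0, 1)).all():
            raise ProtocolError("share phenotype must be 0/1")
        self.data = self.data.astype(np.int8, copy=False)

    @property
    def genotypes(self) -> np.ndarray:
        return self.data[:, :-1]

    @property
    def phenotype(self) -> np.ndarray:
        return self.data[:, -1]

    @property
    def n_rows(self) -> int:
        return self.data.shape[0]

    def to_tsv(self, path) -> None:
        """Headerless integer TSV -- the 2-bits-per-genotype logical payload."""
        np.savetxt(path, self.data, fmt="%d", delimiter="\t")


@dataclass
class SampleRecord:
    """Party-private record needed to unshuffle and to audit exposure."""

    party_id: str
    iteration: int
    batch_index: int
    row_indices: np.ndarray
    row_perm: np.ndarray
    col_perm: np.ndarray
    batch: tuple[str, ...]


class LabelHistory:
    """Per-SNP significance labels across iterations plus the majority label."""

    def __init__(self, snp_ids: Sequence[str]):
        self._labels: dict[str, list[int]] = {s: [] for s in snp_ids}

    def add(self, labels: Mapping[str, int]) -> None:
        missing = set(self._labels) - set(labels)
        if missing or set(labels) - set(self._labels):
            raise ProtocolError("iteration labels do not cover the SNP set")
        for snp, lab in labels.items():
            self._labels[snp].append(int(lab))

    def history(self, snp_id: str) -> list[int]:
        return list(self._labels[snp_id])

    def majority(self) -> dict[str, int]:
        return {s: majority_label(h) for s, h in self._labels.items()}


def majority_label(labels: Sequence[int]) -> int:
    """MODE of the label history; an exact tie resolves to 0 (insignificant)."""
    if not labels:
        raise ProtocolError("empty label history")
    ones = sum(labels)
    return 1 if 2 * ones > len(labels) else 0


def local_screen(
    dataset: PartyDataset, mu: float, intercept: bool = True
) -> set[str]:
    """SNPs locally insignificant at threshold ``mu`` (local Wald p > mu).

    Non-converged fits count as insignificant (logged).  A single-class local
    phenotype makes screening impossible; an empty set is returned with a
    warning so the pooled phase can still proceed.
    """
    y = dataset.phenotypes.labels
    if y.min() == y.max():
        logger.warning(
            "party %s holds a single phenotype class; local screening skipped",
            dataset.party_id,
        )
        return set()
    res = logistic_wald_scan(dataset.genotypes.values, y, intercept=intercept)
    n_unconverged = int((~res.converged).sum())
    if n_unconverged:
        logger.warning(
            "party %s: %d SNPs did not converge locally; counted insignificant",
            dataset.party_id,
            n_unconverged,
        )
    insig = (~res.converged) | (np.nan_to_num(res.p_value, nan=1.0) > mu)
    return {dataset.snp_ids[j] for j in np.flatnonzero(insig)}


def intersect_insignificant(sets: Sequence[set[str]]) -> set[str]:
    """SNPs deemed insignificant by every party."""
    if len(sets) < 2:
        raise ProtocolError("screening intersection needs at least two parties")
    return set.intersection(*(set(s) for s in sets))


def prune(dataset: PartyDataset, insig: set[str]) -> PartyDataset:
    """Remove the mutually insignificant SNP columns, preserving order."""
    unknown = set(insig) - set(dataset.snp_ids)
    if unknown:
        raise ProtocolError(f"cannot prune unknown SNP ids: {sorted(unknown)[:5]}")
    keep = [s for s in dataset.snp_ids if s not in insig]
    return PartyDataset(
        party_id=dataset.party_id,
        genotypes=dataset.genotypes.take_snps(keep),
        phenotypes=dataset.phenotypes,
    )


def plan_iteration(
    remaining_snps: Sequence[str],
    config: ProtocolConfig,
    rng: np.random.Generator,
    chrom: Optional[Mapping[str, str]] = None,
    iteration: int = 1,
) -> IterationPlan:
    """Partition the remaining SNPs into batches of at most ``m``.

    When chromosome tags are available, batches are chromosome-homogeneous
    and the chromosome order rotates with the iteration index, so successive
    iterations lead with different chromosomes.  One fresh column seed is
    drawn per batch.
    """
    snps = list(remaining_snps)
    if not snps:
        raise ProtocolError("cannot plan an iteration with no remaining SNPs")
    if chrom:
        groups: dict[str, list[str]] = {}
        for s in snps:
            groups.setdefault(chrom.get(s, ""), []).append(s)
        keys = sorted(groups)
        keys = keys[(iteration - 1) % len(keys) :] + keys[: (iteration - 1) % len(keys)]
        ordered_groups = [groups[k] for k in keys]
    else:
        ordered_groups = [snps]
    batches: list[tuple[str, ...]] = []
    for group in ordered_groups:
        for i in range(0, len(group), config.m):
            batches.append(tuple(group[i : i + config.m]))
    seeds = [int(rng.integers(0, 2**31 - 1)) for _ in batches]
    return IterationPlan(
        iteration=iteration, batches=batches, column_seeds=seeds, K=config.K
    )


def sample_and_shuffle(
    dataset: PartyDataset,
    batch: Sequence[str],
    K: int,
    column_seed: int,
    party_private_seed: int,
    row_indices: Optional[np.ndarray] = None,
    iteration: int = 1,
    batch_index: int = 0,
) -> tuple[AnonymizedShare, SampleRecord]:
    """Build one party's de-identified block for one batch.

    ``K`` distinct individuals are drawn uniformly without replacement (or
    reused from ``row_indices`` when the party samples once per iteration and
    shares several batches).  Columns are permuted by the permutation derived
    from the common ``column_seed`` -- identical across parties -- and rows by
    a party-private permutation.  The returned :class:`SampleRecord` stays
    with the party; only the share leaves it.
    """
    if not len(batch):
        raise ProtocolError("empty SNP batch")
    n = dataset.n_individuals
    if K > n:
        raise ProtocolError(f"cannot sample K={K} from a party of {n}")
    rng = np.random.default_rng(party_private_seed)
    if row_indices is None:
        row_indices = rng.choice(n, size=K, replace=False)
    else:
        row_indices = np.asarray(row_indices, dtype=int)
        if row_indices.shape[0] != K:
            raise ProtocolError("provided row sample does not have size K")
    col_perm = np.random.default_rng(column_seed).permutation(len(batch))
    sub = dataset.genotypes.take_snps(list(batch)).values[row_indices][:, col_perm]
    row_perm = rng.permutation(K)
    block = np.column_stack(
        [sub[row_perm], dataset.phenotypes.labels[row_indices][row_perm]]
    )
    share = AnonymizedShare(data=block)
    record = SampleRecord(
        party_id=dataset.party_id,
        iteration=iteration,
        batch_index=batch_index,
        row_indices=row_indices,
        row_perm=row_perm,
        col_perm=col_perm,
        batch=tuple(batch),
    )
    return share, record


def server_compute(
    shares: Sequence[AnonymizedShare], intercept: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Pool the shares and return one Wald p-value per (shuffled) column.

    The server sees only identifier-free integer blocks.  Returns
    ``(p_values, converged)`` in the shared column order; a constant pooled
    column yields a non-converged NaN entry without affecting the others.
    """
    if not shares:
        raise ProtocolError("no shares to compute on")
    widths = {s.data.shape[1] for s in shares}
    if len(widths) != 1:
        raise ProtocolError(f"shares disagree on column count: {sorted(widths)}")
    pooled = np.vstack([s.data for s in shares])
    y = pooled[:, -1]
    if y.min() == y.max():
        raise ProtocolError("pooled phenotype contains a single class")
    res = logistic_wald_scan(pooled[:, :-1], y, intercept=intercept)
    return res.p_value, res.converged


def unshuffle_and_label(
    p_values: np.ndarray,
    batch: Sequence[str],
    col_perm: np.ndarray,
    mu: float,
    converged: Optional[np.ndarray] = None,
) -> dict[str, int]:
    """Map shuffled p-values back to SNP ids and threshold them.

    Share column k holds batch SNP ``col_perm[k]``, so the inverse assignment
    is ``p_batch[col_perm] = p_shuffled``.  Label 1 iff p <= mu; NaN or
    non-converged columns label 0.
    """
    p_values = np.asarray(p_values, dtype=float)
    if p_values.shape[0] != len(batch):
        raise ProtocolError(
            f"{p_values.shape[0]} p-values for a batch of {len(batch)}"
        )
    p_orig = np.empty(len(batch))
    p_orig[np.asarray(col_perm)] = p_values
    ok = np.ones(len(batch), dtype=bool)
    if converged is not None:
        ok_shuffled = np.asarray(converged, dtype=bool)
        ok = np.empty(len(batch), dtype=bool)
        ok[np.asarray(col_perm)] = ok_shuffled
    labels = {}
    for j, snp in enumerate(batch):
        p = p_orig[j]
        labels[snp] = int(ok[j] and np.isfinite(p) and p <= mu)
    return labels


def check_stop(
    previous_majority: Optional[Mapping[str, int]],
    current_majority: Mapping[str, int],
    iteration: int,
    config: ProtocolConfig,
) -> tuple[bool, Optional[str]]:
    """Halt when every SNP's majority label is unchanged, or at the cap."""
    if previous_majority is not None:
        if set(previous_majority) != set(current_majority):
            raise ProtocolError("stop check over mismatched SNP sets")
        if all(previous_majority[s] == current_majority[s] for s in current_majority):
            return True, "labels-stable"
    if iteration >= config.max_iterations:
        return True, "max-iterations"
    return False, None


@dataclass
class ProtocolResult:
    """Everything a protocol run produces (and what each party may keep)."""

    final_labels: dict[str, int]
    insignificant_phase1: set[str]
    iterations_run: int
    stop_reason: Optional[str]
    majority_by_iteration: list[dict[str, int]]
    pvalue_trail: list[dict[str, float]]
    exposure: ExposureLog
    audit_log: list[dict]
    server_fits: int = 0
    server_work: int = 0
    sample_records: list[SampleRecord] = field(default_factory=list)

    def significant_snps(self) -> set[str]:
        return {s for s, l in self.final_labels.items() if l == 1}


def run_protocol(
    parties: Sequence[PartyDataset], config: ProtocolConfig
) -> ProtocolResult:
    """Execute both protocol phases over in-process party/server actors.

    Requires at least two parties with identical SNP id sets (columns are
    re-aligned to the first party's order if needed) and ``K`` no larger than
    any party.  All randomness derives from ``config.master_seed`` via named
    substreams.
    """
    parties = list(parties)
    if len(parties) < 2:
        raise ProtocolError("the protocol needs at least two parties")
    ref_ids = parties[0].snp_ids
    for p in parties[1:]:
        if set(p.snp_ids) != set(ref_ids):
            raise ProtocolError(
                f"party {p.party_id!r} SNP set differs from party "
                f"{parties[0].party_id!r}"
            )
    parties = [
        p
        if p.snp_ids == ref_ids
        else PartyDataset(p.party_id, p.genotypes.take_snps(ref_ids), p.phenotypes)
        for p in parties
    ]
    if config.K > min(p.n_individuals for p in parties):
        raise ProtocolError("K exceeds the smallest party size")

    audit_log: list[dict] = []
    # ---- Phase 1: local screening, intersection, pruning -------------------
    insig_sets = [local_screen(p, config.mu_phase1, config.intercept) for p in parties]
    insig = intersect_insignificant(insig_sets)
    pruned = [prune(p, insig) for p in parties]
    remaining = pruned[0].snp_ids
    audit_log.append(
        {
            "event": "phase1",
            "mu": config.mu_phase1,
            "n_snps": len(ref_ids),
            "n_pruned": len(insig),
            "n_remaining": len(remaining),
        }
    )

    exposure = ExposureLog(party_sizes={p.party_id: p.n_individuals for p in parties})
    chrom_map = None
    g0 = parties[0].genotypes
    if g0.chrom is not None:
        chrom_map = dict(zip(g0.snp_ids, g0.chrom))

    if not remaining:
        final = {s: 0 for s in ref_ids}
        return ProtocolResult(
            final_labels=final,
            insignificant_phase1=insig,
            iterations_run=0,
            stop_reason="all-pruned",
            majority_by_iteration=[],
            pvalue_trail=[],
            exposure=exposure,
            audit_log=audit_log,
        )

    # ---- Phase 2: iterative dynamic sampling -------------------------------
    history = LabelHistory(remaining)
    majority_snapshots: list[dict[str, int]] = []
    pvalue_trail: list[dict[str, float]] = []
    records: list[SampleRecord] = []
    server_fits = 0
    server_work = 0
    prev_majority: Optional[dict[str, int]] = None
    stop_reason: Optional[str] = None
    iterations_run = 0
    frozen: dict[str, int] = {}  # optional per-batch freeze carries labels over

    for T in range(1, config.max_iterations + 1):
        iterations_run = T
        plan_rng = substream(config.master_seed, "plan", T)
        plan = plan_iteration(remaining, config, plan_rng, chrom=chrom_map, iteration=T)
        exposure.column_seeds.append(tuple(plan.column_seeds))
        row_samples = {}
        for p in parties:
            rows = substream(config.master_seed, "rows", p.party_id, T).choice(
                p.n_individuals, size=config.K, replace=False
            )
            row_samples[p.party_id] = rows
            exposure.record(p.party_id, rows)
        iter_labels: dict[str, int] = {}
        iter_pvals: dict[str, float] = {}
        n_frozen_batches = 0
        for b, (batch, seed) in enumerate(zip(plan.batches, plan.column_seeds)):
            if config.freeze_stable_batches and _batch_frozen(batch, history):
                for s in batch:
                    iter_labels[s] = frozen.get(s, 0)
                    iter_pvals[s] = float("nan")
                n_frozen_batches += 1
                continue
            shares = []
            for p in parties:
                share, rec = sample_and_shuffle(
                    p,
                    batch,
                    config.K,
                    column_seed=seed,
                    party_private_seed=subseed(
                        config.master_seed, "rowperm", p.party_id, T, b
                    ),
                    row_indices=row_samples[p.party_id],
                    iteration=T,
                    batch_index=b,
                )
                shares.append(share)
                records.append(rec)
            p_shuffled, conv = server_compute(shares, intercept=config.intercept)
            server_fits += len(batch)
            server_work += sum(s.n_rows for s in shares) * len(batch)
            col_perm = records[-1].col_perm  # common to all parties by seed
            labels_b = unshuffle_and_label(
                p_shuffled, batch, col_perm, config.mu_phase2, converged=conv
            )
            iter_labels.update(labels_b)
            p_orig = np.empty(len(batch))
            p_orig[col_perm] = p_shuffled
            iter_pvals.update(dict(zip(batch, p_orig)))
        history.add(iter_labels)
        frozen = iter_labels
        current_majority = history.majority()
        majority_snapshots.append(current_majority)
        pvalue_trail.append(iter_pvals)
        flips = (
            sum(
                prev_majority[s] != current_majority[s] for s in current_majority
            )
            if prev_majority is not None
            else len(current_majority)
        )
        stop, stop_reason = check_stop(prev_majority, current_majority, T, config)
        audit_log.append(
            {
                "event": "iteration",
                "iteration": T,
                "n_batches": len(plan.batches),
                "n_frozen_batches": n_frozen_batches,
                "column_seeds": list(plan.column_seeds),
                "K": config.K,
                "label_flips": flips,
                "stop": stop,
                "stop_reason": stop_reason,
            }
        )
        prev_majority = current_majority
        if stop:
            break

    final = {s: 0 for s in insig}
    final.update(prev_majority or {})
    final = {s: final[s] for s in ref_ids}  # restore input column order
    return ProtocolResult(
        final_labels=final,
        insignificant_phase1=insig,
        iterations_run=iterations_run,
        stop_reason=stop_reason,
        majority_by_iteration=majority_snapshots,
        pvalue_trail=pvalue_trail,
        exposure=exposure,
        audit_log=audit_log,
        server_fits=server_fits,
        server_work=server_work,
        sample_records=records,
    )


def _batch_frozen(batch: Sequence[str], history: LabelHistory) -> bool:
    """A batch freezes when every SNP's labels were unanimous and unchanged
    across the last two iterations (opt-in behaviour, off by default)."""
    for s in batch:
        h = history.history(s)
        if len(h) < 2 or h[-1] != h[-2]:
            return False
    return True
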