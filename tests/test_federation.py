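"""Protocol mechanics: screening, batching, shuffling, voting, stopping, and
the pooled-oracle equivalence that anchors end-to-end correctness."""

import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tdsgwas.assoc_tests import run_single_snp_scan
from tdsgwas.errors import ProtocolError
from tdsgwas.federation import (
    ProtocolConfig,
    check_stop,
    intersect_insignificant,
    local_screen,
    majority_label,
    plan_iteration,
    prune,
    run_protocol,
    sample_and_shuffle,
    server_compute,
    unshuffle_and_label,
)
from tdsgwas.synthetic_cohorts import PartyDataset, PhenotypeVector
from conftest import make_party


class TestLocalScreen:
    def test_threshold_boundaries(self, small_party):
        assert local_screen(small_party, mu=1.0) == set()
        assert local_screen(small_party, mu=1e-300) == set(small_party.snp_ids)

    def test_matches_scan_oracle(self, small_party):
        results = run_single_snp_scan(small_party)
        expected = {r.snp_id for r in results if (not r.converged) or r.p_value > 0.3}
        assert local_screen(small_party, mu=0.3) == expected

    def test_single_class_party_screens_nothing(self, small_party):
        degenerate = PartyDataset(
            "X",
            small_party.genotypes,
            PhenotypeVector(labels=np.ones(small_party.n_individuals, dtype=int)),
        )
        assert local_screen(degenerate, mu=0.3) == set()


class TestIntersectAndPrune:
    @pytest.mark.parametrize(
        "sets, expected",
        [
            ([{"a", "b", "c"}, {"b", "c", "d"}], {"b", "c"}),
            ([{"a", "b"}, set()], set()),
            ([{"a", "b"}, {"b", "c"}, {"b"}], {"b"}),
        ],
    )
    def test_intersection(self, sets, expected):
        assert intersect_insignificant(sets) == expected

    def test_needs_two_parties(self):
        with pytest.raises(ProtocolError):
            intersect_insignificant([{"a"}])

    def test_prune_identity_and_order(self, small_party):
        same = prune(small_party, set())
        assert same.snp_ids == small_party.snp_ids
        assert np.array_equal(same.genotypes.values, small_party.genotypes.values)
        pruned = prune(small_party, {"snp1", "snp3"})
        assert pruned.snp_ids == [
            s for s in small_party.snp_ids if s not in ("snp1", "snp3")
        ]

    def test_prune_everything_is_valid(self, small_party):
        empty = prune(small_party, set(small_party.snp_ids))
        assert empty.genotypes.n_snps == 0
        assert empty.n_individuals == small_party.n_individuals

    def test_prune_unknown_id_rejected(self, small_party):
        with pytest.raises(ProtocolError):
            prune(small_party, {"nope"})


class TestPlanIteration:
    def test_partition_sizes_disjoint_covering(self):
        snps = [f"s{i}" for i in range(700)]
        cfg = ProtocolConfig(K=10, m=300)
        plan = plan_iteration(snps, cfg, np.random.default_rng(0))
        assert [len(b) for b in plan.batches] == [300, 300, 100]
        flat = [s for b in plan.batches for s in b]
        assert sorted(flat) == sorted(snps)
        assert len(plan.column_seeds) == 3

    def test_single_snp(self):
        cfg = ProtocolConfig(K=5, m=300)
        plan = plan_iteration(["only"], cfg, np.random.default_rng(1))
        assert plan.batches == [("only",)]

    def test_chromosome_homogeneous_batches(self):
        snps = [f"s{i}" for i in range(40)]
        chrom = {s: ("chr1" if i < 23 else "chr2") for i, s in enumerate(snps)}
        cfg = ProtocolConfig(K=5, m=10)
        for seed in range(100):
            plan = plan_iteration(
                snps, cfg, np.random.default_rng(seed), chrom=chrom, iteration=seed + 1
            )
            for batch in plan.batches:
                assert len({chrom[s] for s in batch}) == 1


class TestSampleAndShuffle:
    def test_deterministic_and_identifier_free(self, small_party):
        batch = small_party.snp_ids[:4]
        a, rec_a = sample_and_shuffle(small_party, batch, K=20, column_seed=3, party_private_seed=7)
        b, _ = sample_and_shuffle(small_party, batch, K=20, column_seed=3, party_private_seed=7)
        assert np.array_equal(a.data, b.data)
        buf = io.StringIO()
        a.to_tsv(buf)
        text = buf.getvalue()
        for token in small_party.snp_ids + small_party.genotypes.individual_ids:
            assert token not in text

    def test_share_reconstructs_with_private_record(self, small_party):
        batch = small_party.snp_ids[2:8]
        K = small_party.n_individuals  # degenerate: every row shared
        share, rec = sample_and_shuffle(
            small_party, batch, K=K, column_seed=11, party_private_seed=5
        )
        sub = small_party.genotypes.take_snps(batch).values[rec.row_indices]
        expected = sub[:, rec.col_perm][rec.row_perm]
        assert np.array_equal(share.genotypes, expected)
        assert np.array_equal(
            share.phenotype,
            small_party.phenotypes.labels[rec.row_indices][rec.row_perm],
        )

    def test_common_seed_gives_common_column_permutation(self, two_parties):
        batch = two_parties[0].snp_ids[:6]
        for seed in range(20):
            recs = [
                sample_and_shuffle(
                    p, batch, K=30, column_seed=seed, party_private_seed=100 + i
                )[1]
                for i, p in enumerate(two_parties)
            ]
            assert np.array_equal(recs[0].col_perm, recs[1].col_perm)

    def test_oversampling_and_empty_batch_rejected(self, small_party):
        with pytest.raises(ProtocolError):
            sample_and_shuffle(
                small_party, small_party.snp_ids[:2], K=10_000, column_seed=0,
                party_private_seed=0,
            )
        with pytest.raises(ProtocolError):
            sample_and_shuffle(
                small_party, [], K=5, column_seed=0, party_private_seed=0
            )


class TestServerCompute:
    def test_full_shares_equal_pooled_scan(self, two_parties):
        batch = two_parties[0].snp_ids
        shares, recs = [], []
        for i, p in enumerate(two_parties):
            s, r = sample_and_shuffle(
                p, batch, K=p.n_individuals, column_seed=42, party_private_seed=i
            )
            shares.append(s)
            recs.append(r)
        p_shuffled, conv = server_compute(shares)
        p_unshuffled = np.empty_like(p_shuffled)
        p_unshuffled[recs[0].col_perm] = p_shuffled
        direct = run_single_snp_scan(two_parties)
        assert np.allclose(p_unshuffled, [r.p_value for r in direct], atol=1e-9)

    def test_case_only_and_control_only_parties_pool_fine(self):
        cases = make_party("A", n_individuals=50, seed=1, case_fraction=1.0)
        controls = make_party("B", n_individuals=50, seed=2, case_fraction=0.0)
        batch = cases.snp_ids
        shares = [
            sample_and_shuffle(p, batch, K=50, column_seed=9, party_private_seed=i)[0]
            for i, p in enumerate((cases, controls))
        ]
        pvals, conv = server_compute(shares)
        assert np.isfinite(pvals[conv]).all()
        assert conv.sum() > 0

    def test_constant_pooled_column_isolated(self, two_parties):
        for p in two_parties:
            p.genotypes.values[:, 3] = 2
        batch = two_parties[0].snp_ids
        shares, recs = [], []
        for i, p in enumerate(two_parties):
            s, r = sample_and_shuffle(
                p, batch, K=40, column_seed=1, party_private_seed=i
            )
            shares.append(s)
            recs.append(r)
        pvals, conv = server_compute(shares)
        col = int(np.flatnonzero(np.asarray(recs[0].col_perm) == 3)[0])
        assert not conv[col]
        assert conv.sum() == len(batch) - 1

    def test_single_class_pool_raises(self):
        a = make_party("A", n_individuals=20, seed=1, case_fraction=1.0)
        b = make_party("B", n_individuals=20, seed=2, case_fraction=1.0)
        shares = [
            sample_and_shuffle(p, a.snp_ids, K=20, column_seed=0, party_private_seed=i)[0]
            for i, p in enumerate((a, b))
        ]
        with pytest.raises(ProtocolError):
            server_compute(shares)


class TestUnshuffleAndLabel:
    def test_threshold_semantics_identity_perm(self):
        labels = unshuffle_and_label(
            np.array([0.2, 0.4]), ["snp1", "snp2"], np.array([0, 1]), mu=0.3
        )
        assert labels == {"snp1": 1, "snp2": 0}

    def test_inversion_bookkeeping(self):
        # share column 0 holds snp2 (perm[0]=1), column 1 holds snp1
        labels = unshuffle_and_label(
            np.array([0.4, 0.2]), ["snp1", "snp2"], np.array([1, 0]), mu=0.3
        )
        assert labels == {"snp1": 1, "snp2": 0}

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(min_value=1, max_value=30), st.integers(min_value=0, max_value=10**6))
    def test_shuffle_unshuffle_roundtrip(self, m, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=m)
        perm = rng.permutation(m)
        snps = [f"s{i}" for i in range(m)]
        labels = unshuffle_and_label(p[perm], snps, perm, mu=0.5)
        expected = {s: int(p[i] <= 0.5) for i, s in enumerate(snps)}
        assert labels == expected

    def test_length_mismatch_rejected(self):
        with pytest.raises(ProtocolError):
            unshuffle_and_label(np.array([0.5]), ["a", "b"], np.array([0, 1]), mu=0.3)


class TestVotingAndStopping:
    @pytest.mark.parametrize(
        "history, expected",
        [((1, 0, 1), 1), ((1, 0), 0), ((0, 0, 0), 0), ((1, 1, 0, 0), 0), ((1,), 1)],
    )
    def test_majority_mode_with_tie_to_zero(self, history, expected):
        assert majority_label(history) == expected

    def test_empty_history_rejected(self):
        with pytest.raises(ProtocolError):
            majority_label([])

    def test_stop_on_stable_labels(self):
        cfg = ProtocolConfig(K=5, max_iterations=9)
        stop, reason = check_stop({"a": 1, "b": 0}, {"a": 1, "b": 0}, 3, cfg)
        assert stop and reason == "labels-stable"

    def test_continue_on_any_flip(self):
        cfg = ProtocolConfig(K=5, max_iterations=9)
        stop, _ = check_stop({"a": 1, "b": 0}, {"a": 1, "b": 1}, 3, cfg)
        assert not stop

    def test_max_iterations_cap(self):
        cfg = ProtocolConfig(K=5, max_iterations=4)
        stop, reason = check_stop({"a": 1}, {"a": 0}, 4, cfg)
        assert stop and reason == "max-iterations"

    def test_mismatched_snp_sets_rejected(self):
        cfg = ProtocolConfig(K=5)
        with pytest.raises(ProtocolError):
            check_stop({"a": 1}, {"b": 1}, 2, cfg)


class TestRunProtocol:
    def test_pooled_oracle_equivalence(self, small_study):
        parties, _ = small_study
        mu = 0.3
        cfg = ProtocolConfig(
            K=parties[0].n_individuals,
            mu_phase1=1.0,  # phase 1 disabled: nothing exceeds p > 1
            mu_phase2=mu,
            m=10**6,
            max_iterations=1,
            master_seed=123,
        )
        result = run_protocol(parties, cfg)
        pooled = run_single_snp_scan(parties)
        expected = {
            r.snp_id: int(r.converged and r.p_value <= mu) for r in pooled
        }
        assert result.final_labels == expected

    def test_shuffle_invariance_with_full_sampling(self, small_study):
        parties, _ = small_study
        base = dict(
            K=parties[0].n_individuals, mu_phase1=1.0, m=40, max_iterations=1
        )
        r1 = run_protocol(parties, ProtocolConfig(master_seed=1, **base))
        r2 = run_protocol(parties, ProtocolConfig(master_seed=99, **base))
        assert r1.final_labels == r2.final_labels
        for s in r1.pvalue_trail[0]:
            assert r1.pvalue_trail[0][s] == pytest.approx(
                r2.pvalue_trail[0][s], abs=1e-9
            )

    def test_all_snps_pruned_short_circuits(self, two_parties):
        # a sub-atomic mu makes every local p exceed it -> everything pruned
        cfg = ProtocolConfig(K=10, mu_phase1=1e-300, master_seed=0)
        result = run_protocol(two_parties, cfg)
        assert result.iterations_run == 0
        assert set(result.final_labels.values()) == {0}
        assert result.stop_reason == "all-pruned"

    def test_screening_monotone_in_threshold(self, two_parties):
        loose = run_protocol(
            two_parties, ProtocolConfig(K=10, mu_phase1=0.2, max_iterations=1)
        ).insignificant_phase1
        strict = run_protocol(
            two_parties, ProtocolConfig(K=10, mu_phase1=0.6, max_iterations=1)
        ).insignificant_phase1
        assert strict <= loose

    def test_server_work_accounting(self, small_study):
        parties, _ = small_study
        cfg = ProtocolConfig(
            K=50, mu_phase1=1.0, mu_phase2=0.3, m=30, max_iterations=3,
            master_seed=5,
        )
        result = run_protocol(parties, cfg)
        n_remaining = len(parties[0].snp_ids)
        T = result.iterations_run
        assert result.server_fits == T * n_remaining
        assert result.server_work == T * n_remaining * cfg.K * len(parties)

    def test_seed_reproducibility(self, small_study):
        parties, _ = small_study
        cfg = ProtocolConfig(K=60, max_iterations=3, master_seed=77)
        a = run_protocol(parties, cfg)
        b = run_protocol(parties, cfg)
        assert a.final_labels == b.final_labels
        assert a.pvalue_trail == b.pvalue_trail

    def test_misaligned_snp_sets_rejected(self, two_parties):
        a, b = two_parties
        clipped = PartyDataset(
            "B", b.genotypes.take_snps(b.snp_ids[:-1]), b.phenotypes
        )
        with pytest.raises(ProtocolError):
            run_protocol([a, clipped], ProtocolConfig(K=5))

    def test_exposure_log_populated(self, small_study):
        parties, _ = small_study
        cfg = ProtocolConfig(K=40, max_iterations=2, master_seed=3)
        result = run_protocol(parties, cfg)
        for p in parties:
            draws = result.exposure.samples[p.party_id]
            assert len(draws) == result.iterations_run
            for idx in draws:
                assert len(idx) == 40
                assert len(set(idx.tolist())) == 40
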