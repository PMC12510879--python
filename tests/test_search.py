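"""The two-stage pipeline: masking, E-values, streaming, partitioning,
iterative profile search."""

from decimal import Decimal, getcontext

import numpy as np
import pytest

import profsearch as ps

from conftest import random_records


def hit_key(h):
    return (
        h.target_id,
        h.gapless_score,
        h.gapped.score,
        h.evalue,
        h.gapped.query_interval,
        h.gapped.target_interval,
        tuple(h.gapped.ops),
    )


@pytest.fixture(scope="module")
def planted_fixture(blosum62):
    """99 random decoys + 1 planted 80%-identity homolog of the query."""
    rng = np.random.default_rng(42)
    decoys = random_records(99, rng, min_len=60, max_len=200, prefix="decoy")
    query = random_records(1, rng, min_len=150, max_len=150, prefix="query")[0]
    homolog = ps.mutate_homolog(query, 0.8, seed=42, record_id="planted")
    db = ps.build_packed_db(decoys + [homolog])
    return query, db


class TestMasking:
    def test_poly_a_fully_masked(self):
        seq = ps.encode_sequence("A" * 50)
        masked = ps.mask_low_complexity(seq, window=12, entropy_threshold=2.0)
        assert (masked.codes == ps.X_INDEX).all()

    def test_random_sequence_unchanged(self):
        rng = np.random.default_rng(8)
        rec = random_records(1, rng, min_len=200, max_len=200)[0]
        seq = ps.encode_sequence(rec)
        masked = ps.mask_low_complexity(seq, window=12, entropy_threshold=2.0)
        assert np.array_equal(masked.codes, seq.codes)

    def test_masked_positions_score_as_x(self, blosum62):
        seq = ps.encode_sequence("WKDYE" + "A" * 30 + "WKDYE")
        masked = ps.mask_low_complexity(seq, window=12, entropy_threshold=2.0)
        P = ps.pssm_from_sequence("WWWW", blosum62)
        x_col = ps.X_INDEX
        for j in np.nonzero(masked.codes == x_col)[0]:
            assert P.scores[0, masked.codes[j]] == P.scores[0, x_col]

    def test_window_validation(self):
        with pytest.raises(ValueError):
            ps.mask_low_complexity(ps.encode_sequence("ACD"), window=0)


class TestEvalue:
    def test_score_zero_is_maximal(self):
        assert ps.compute_evalue(0, 100, 10**6, 0.267, 0.041) == pytest.approx(
            0.041 * 100 * 10**6
        )

    def test_exponential_decay_identity(self):
        s = 37
        e1 = ps.compute_evalue(s, 50, 10**5)
        e2 = ps.compute_evalue(2 * s, 50, 10**5)
        assert e2 / e1 == pytest.approx(np.exp(-0.267 * s), rel=1e-12)

    def test_against_arbitrary_precision_oracle(self):
        getcontext().prec = 60
        lam, k, m, n, s = Decimal("0.267"), Decimal("0.041"), 100, 10**6, 100
        expected = k * m * n * (-lam * s).exp()
        got = ps.compute_evalue(100, 100, 10**6, 0.267, 0.041)
        assert got == pytest.approx(float(expected), rel=1e-12)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            ps.compute_evalue(10, 100, 1000, lam=0.0)
        with pytest.raises(ValueError):
            ps.compute_evalue(10, 100, 1000, k_param=-1.0)


class TestTwoStage:
    def test_filter_disabled_equals_exhaustive(self, blosum62, planted_fixture):
        query, db = planted_fixture
        params = ps.SearchParams(filter_threshold=0, max_seqs=db.n_sequences)
        hits = ps.two_stage_search(query, db, params, blosum62)
        # independent exhaustive gapped search over every database sequence
        P = ps.pssm_from_sequence(ps.encode_sequence(query), blosum62)
        exhaustive = []
        for i in range(db.n_sequences):
            t = db.sequence(i)
            a = ps.gotoh_align(P, t, params.penalties)
            ev = ps.compute_evalue(a.score, P.query_length, db.total_residues)
            if ev <= params.evalue_cutoff:
                exhaustive.append((ev, t.id, a.score))
        exhaustive.sort(key=lambda x: (x[0], x[1]))
        assert [(h.evalue, h.target_id, h.gapped.score) for h in hits] == exhaustive

    def test_planted_homolog_ranks_first(self, blosum62, planted_fixture):
        query, db = planted_fixture
        hits = ps.two_stage_search(query, db, ps.SearchParams(), blosum62)
        assert hits[0].target_id == "planted"

    def test_empty_candidate_set(self, blosum62, planted_fixture):
        query, db = planted_fixture
        params = ps.SearchParams(filter_threshold=10_000)
        assert ps.two_stage_search(query, db, params, blosum62) == []

    def test_threshold_monotonicity(self, blosum62, planted_fixture):
        query, db = planted_fixture
        ids_low = {
            h.target_id
            for h in ps.two_stage_search(
                query, db, ps.SearchParams(filter_threshold=5), blosum62
            )
        }
        ids_high = {
            h.target_id
            for h in ps.two_stage_search(
                query, db, ps.SearchParams(filter_threshold=40), blosum62
            )
        }
        assert ids_high <= ids_low

    def test_saturated_scores_always_admitted(self, blosum62):
        rng = np.random.default_rng(55)
        parents = random_records(6, rng, min_len=150, max_len=200, prefix="p")
        homs = [
            ps.mutate_homolog(parents[0], 0.95, seed=i, record_id=f"hom{i}")
            for i in range(5)
        ]
        db = ps.build_packed_db(homs + parents[1:])
        # cap stage 2 to a single candidate: saturated homologs must still
        # all reach stage 2
        params = ps.SearchParams(max_seqs=1, filter_threshold=0)
        hits = ps.two_stage_search(parents[0], db, params, blosum62)
        sat_ids = {h.target_id for h in hits if h.gapless_score == 255}
        assert {f"hom{i}" for i in range(5)} <= sat_ids

    def test_gapless_bounded_by_gapped_in_full_mode(self, blosum62, planted_fixture):
        query, db = planted_fixture
        params = ps.SearchParams(filter_mode="full", filter_threshold=0,
                                 max_seqs=db.n_sequences)
        for h in ps.two_stage_search(query, db, params, blosum62):
            assert h.gapless_score <= h.gapped.score

    def test_empty_db_rejected(self, blosum62, planted_fixture):
        query, db = planted_fixture
        empty = db.subset(0, 0)
        with pytest.raises(ValueError):
            ps.two_stage_search(query, empty, ps.SearchParams(), blosum62)


class TestStreaming:
    def test_single_batch_equals_unbatched(self, blosum62, planted_fixture):
        query, db = planted_fixture
        params = ps.SearchParams()
        base = ps.two_stage_search(query, db, params, blosum62)
        streamed = ps.search_streamed(
            query, db, params, batch_residues=db.total_residues, matrix=blosum62
        )
        assert list(map(hit_key, streamed)) == list(map(hit_key, base))

    @pytest.mark.parametrize("fraction", [1, 4, 16])
    def test_batch_sizes_agree(self, fraction, blosum62, planted_fixture):
        query, db = planted_fixture
        params = ps.SearchParams()
        base = ps.two_stage_search(query, db, params, blosum62)
        size = max(db.total_residues // fraction, int(db.lengths.max()))
        streamed = ps.search_streamed(
            query, db, params, batch_residues=size, matrix=blosum62
        )
        assert list(map(hit_key, streamed)) == list(map(hit_key, base))

    def test_batch_smaller_than_longest_rejected(self, blosum62, planted_fixture):
        query, db = planted_fixture
        with pytest.raises(ValueError, match="longest"):
            ps.search_streamed(
                query, db, ps.SearchParams(),
                batch_residues=int(db.lengths.max()) - 1, matrix=blosum62,
            )

    def test_db_of_one_sequence(self, blosum62):
        rng = np.random.default_rng(60)
        rec = random_records(1, rng, min_len=80, max_len=80)[0]
        db = ps.build_packed_db([rec])
        params = ps.SearchParams(filter_threshold=0)
        base = ps.two_stage_search(rec, db, params, blosum62)
        streamed = ps.search_streamed(rec, db, params, batch_residues=80,
                                      matrix=blosum62)
        assert list(map(hit_key, streamed)) == list(map(hit_key, base))


class TestPartitioning:
    @pytest.mark.parametrize("n", [1, 2, 4, 8])
    def test_partition_counts_agree(self, n, blosum62, planted_fixture):
        query, db = planted_fixture
        params = ps.SearchParams()
        base = ps.two_stage_search(query, db, params, blosum62)
        split = ps.search_partitioned(query, db, params, n_partitions=n,
                                      matrix=blosum62)
        assert list(map(hit_key, split)) == list(map(hit_key, base))

    def test_one_sequence_per_partition(self, blosum62):
        rng = np.random.default_rng(61)
        records = random_records(12, rng, min_len=40, max_len=120)
        db = ps.build_packed_db(records)
        params = ps.SearchParams(filter_threshold=0, max_seqs=12)
        base = ps.two_stage_search(records[0], db, params, blosum62)
        split = ps.search_partitioned(records[0], db, params, n_partitions=12,
                                      matrix=blosum62)
        assert list(map(hit_key, split)) == list(map(hit_key, base))

    def test_too_many_partitions_rejected(self, blosum62, planted_fixture):
        query, db = planted_fixture
        with pytest.raises(ValueError):
            ps.search_partitioned(query, db, ps.SearchParams(),
                                  n_partitions=db.n_sequences + 1, matrix=blosum62)

    def test_per_partition_cap_still_globally_correct(self, blosum62):
        """max_seqs caps each partition, but the merge re-ranks globally."""
        rng = np.random.default_rng(62)
        parent = random_records(1, rng, min_len=150, max_len=150)[0]
        homs = [
            ps.mutate_homolog(parent, 0.7, seed=i, record_id=f"h{i}")
            for i in range(20)
        ]
        db = ps.build_packed_db(homs)
        params = ps.SearchParams(filter_threshold=0, max_seqs=5,
                                 filter_mode="full")
        base = ps.two_stage_search(parent, db, params, blosum62)
        for n in (2, 4):
            split = ps.search_partitioned(parent, db, params, n_partitions=n,
                                          matrix=blosum62)
            assert list(map(hit_key, split)) == list(map(hit_key, base))


class TestIterative:
    def test_single_round_equals_two_stage(self, blosum62, planted_fixture):
        query, db = planted_fixture
        params = ps.SearchParams(iterations=1)
        rounds, pssm = ps.iterative_search(query, db, params, blosum62)
        base = ps.two_stage_search(query, db, params, blosum62)
        assert list(map(hit_key, rounds[0])) == list(map(hit_key, base))
        assert np.array_equal(
            pssm.scores,
            ps.pssm_from_sequence(ps.encode_sequence(query), blosum62).scores,
        )

    def test_profile_updates_after_round_one(self, blosum62):
        rng = np.random.default_rng(64)
        parent = random_records(1, rng, min_len=150, max_len=150)[0]
        homs = [
            ps.mutate_homolog(parent, 0.85, seed=i, record_id=f"h{i}")
            for i in range(5)
        ]
        decoys = random_records(30, rng, min_len=100, max_len=200, prefix="d")
        db = ps.build_packed_db(homs + decoys)
        params = ps.SearchParams(iterations=2)
        rounds, pssm2 = ps.iterative_search(parent, db, params, blosum62)
        base = ps.pssm_from_sequence(ps.encode_sequence(parent), blosum62)
        assert not np.array_equal(pssm2.scores, base.scores)
        assert len(rounds) == 2

    def test_remote_homology_iteration_not_worse(self, blosum62):
        bench = ps.remote_homology_benchmark(7)
        db = ps.build_packed_db(bench.references)
        params = ps.SearchParams(iterations=2)
        per_round = [{}, {}]
        for q in bench.queries:
            rounds, _ = ps.iterative_search(q, db, params, blosum62)
            per_round[0][q.id] = rounds[0]
            per_round[1][q.id] = rounds[1]
        m1, _ = ps.evaluate_sensitivity(per_round[0], bench.annotation)
        m2, _ = ps.evaluate_sensitivity(per_round[1], bench.annotation)
        assert m2 >= m1
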