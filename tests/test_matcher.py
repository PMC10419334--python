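"""Matcher unit tests: index, seed-and-extend, oracle, host subtraction, coverage."""

import numpy as np
import pytest

from metawave.errors import ConfigError, InputError
from metawave.matcher import (
    MatchHit,
    MatchParams,
    brute_force_matches,
    build_index,
    coverage_report,
    encode_read,
    find_matches,
    match_read,
    subtract_host,
)
from metawave.simdata import generate_genome, simulate_reads, ReadSimParams
from metawave.wave_codec import EncodingProfile, WaveIdentity, encode_sequence

BIN_SYMBOLS = "123456789ABCDEFGHIJZ"


def ident(code, profile, channel=None):
    channel = channel or profile.channels[0]
    return WaveIdentity(channel=channel, code=code, source_length=10 * len(code),
                        profile_id=profile.profile_id)


class TestBuildIndex:
    def test_postings_enumerate_substrings(self, make_db, default_profile):
        db = make_db({"ref1": "1231231212"})
        index = build_index(db, MatchParams(seed_len=4, min_hit_len=4))
        assert index.postings["3123"] == [("ref1", 2)]
        assert index.postings["1231"] == [("ref1", 0), ("ref1", 3)]
        n_kmers = sum(len(v) for v in index.postings.values())
        assert n_kmers == 10 - 4 + 1

    def test_empty_database(self, make_db):
        index = build_index(make_db({}), MatchParams(seed_len=4, min_hit_len=4))
        assert index.postings == {}

    def test_short_reference_skipped(self, make_db, caplog):
        db = make_db({"ref1": "12"})
        with caplog.at_level("WARNING"):
            index = build_index(db, MatchParams(seed_len=4, min_hit_len=4))
        assert index.postings == {}
        assert "skipped" in caplog.text


class TestFindMatches:
    def test_exact_seed_hit(self, make_db, default_profile):
        db = make_db({"ref1": "1231231212"})
        params = MatchParams(seed_len=4, tolerance=0, min_hit_len=4)
        index = build_index(db, params)
        hits = find_matches(ident("3123", default_profile), index, db, params)
        assert len(hits) == 1
        h = hits[0]
        assert (h.ref_offset, h.length, h.mismatches) == (2, 4, 0)

    def test_absent_symbols_no_hits(self, make_db, default_profile):
        db = make_db({"ref1": "1231231212"})
        params = MatchParams(seed_len=4, tolerance=0, min_hit_len=4)
        index = build_index(db, params)
        assert find_matches(ident("9999", default_profile), index, db, params) == []

    def test_tolerant_extension(self, make_db, default_profile):
        db = make_db({"ref1": "1231231212"})
        params = MatchParams(seed_len=4, tolerance=1, min_hit_len=4,
                             adjacent_free=False)
        index = build_index(db, params)
        hits = find_matches(ident("31234", default_profile), index, db, params)
        assert [(h.ref_offset, h.length, h.mismatches) for h in hits] == [(2, 5, 1)]

    def test_adjacent_rank_mismatch_free(self, make_db, default_profile):
        # read differs from the reference by one adjacent-rank symbol (2 vs 1)
        db = make_db({"ref1": "123412341234"})
        params = MatchParams(seed_len=4, tolerance=0, min_hit_len=5,
                             adjacent_free=True)
        index = build_index(db, params)
        hits = find_matches(ident("12342234", default_profile), index, db, params)
        assert hits and hits[0].mismatches == 0
        assert hits[0].length == 8

    def test_profile_mismatch_rejected(self, make_db, default_profile):
        db = make_db({"ref1": "1231231212"})
        params = MatchParams(seed_len=4, min_hit_len=4)
        index = build_index(db, params)
        other = EncodingProfile(slice_stride=2)
        with pytest.raises(ConfigError):
            find_matches(ident("3123", other), index, db, params)

    def test_score_sorting_and_cap(self, make_db, default_profile):
        db = make_db({"ref1": "12341234", "ref2": "123412341234"})
        params = MatchParams(seed_len=4, tolerance=0, min_hit_len=4,
                             max_hits_per_read=1)
        index = build_index(db, params)
        hits = find_matches(ident("12341234", default_profile), index, db, params)
        assert len(hits) == 1
        assert hits[0].ref_id == "ref1"  # equal-length match; ref_id tie-break
        assert hits[0].score == hits[0].length  # no mismatches


class TestBruteForceOracle:
    def test_matches_indexed_example(self, make_db, default_profile):
        db = make_db({"ref1": "1231231212"})
        params = MatchParams(seed_len=4, tolerance=0, min_hit_len=4,
                             adjacent_free=False)
        index = build_index(db, params)
        read = ident("3123", default_profile)
        assert brute_force_matches(read, db, params) == find_matches(read, index, db, params)

    def test_read_longer_than_references(self, make_db, default_profile):
        db = make_db({"ref1": "1231"})
        params = MatchParams(seed_len=4, tolerance=0, min_hit_len=6)
        assert brute_force_matches(ident("12312312", default_profile), db, params) == []

    def test_empty_read(self, make_db, default_profile):
        db = make_db({"ref1": "1231231212"})
        params = MatchParams(seed_len=4, min_hit_len=4)
        assert brute_force_matches(ident("", default_profile), db, params) == []

    def test_equivalence_on_random_instances(self, make_db, default_profile, rng):
        """Spot-check; the full 200-case battery runs in the acceptance suite."""
        params = MatchParams(seed_len=5, tolerance=0, min_hit_len=6,
                             adjacent_free=False)
        for _ in range(25):
            db = make_db({
                f"ref{i}": "".join(rng.choice(list(BIN_SYMBOLS[:6]), size=60))
                for i in range(3)
            })
            index = build_index(db, params)
            read = ident("".join(rng.choice(list(BIN_SYMBOLS[:6]), size=20)),
                         default_profile)
            assert find_matches(read, index, db, params) == \
                brute_force_matches(read, db, params)

    def test_indexed_subset_of_oracle_with_tolerance(self, make_db,
                                                     default_profile, rng):
        params = MatchParams(seed_len=5, tolerance=2, min_hit_len=6,
                             adjacent_free=True)
        for _ in range(25):
            db = make_db({
                f"ref{i}": "".join(rng.choice(list(BIN_SYMBOLS[:6]), size=60))
                for i in range(3)
            })
            index = build_index(db, params)
            read = ident("".join(rng.choice(list(BIN_SYMBOLS[:6]), size=20)),
                         default_profile)
            found = find_matches(read, index, db, params, merge=False)
            oracle = brute_force_matches(read, db, params, merge=False)
            oracle_keys = {(h.ref_id, h.ref_offset, h.read_offset, h.length,
                            h.mismatches) for h in oracle}
            for h in found:
                assert (h.ref_id, h.ref_offset, h.read_offset, h.length,
                        h.mismatches) in oracle_keys


class TestHostSubtraction:
    def test_host_reads_removed_and_foreign_retained(self):
        profile = EncodingProfile()
        params = MatchParams(tolerance=0, adjacent_free=False)
        host = generate_genome(50_000, 0.5, seed=11, record_id="host")
        from metawave.seq_io import CompressedDatabase, DbRecord
        host_db = CompressedDatabase(profile, [
            DbRecord("host", len(host.seq), encode_sequence(host.seq, profile)),
        ])
        host_reads, _ = simulate_reads(host, ReadSimParams(n_reads=30, seed=12))
        foreign = generate_genome(50_000, 0.5, seed=13, record_id="other")
        foreign_reads, _ = simulate_reads(foreign, ReadSimParams(n_reads=30, seed=14))
        encoded = [encode_read(f"h_{r.id}", r.seq, profile) for r in host_reads]
        encoded += [encode_read(f"f_{r.id}", r.seq, profile) for r in foreign_reads]
        kept, removed = subtract_host(encoded, host_db, params)
        kept_ids = {e.read_id for e in kept}
        # every host read removed; foreign reads near-all retained (chance
        # 12-symbol identity matches remove an occasional foreign read)
        assert not any(rid.startswith("h_") for rid in kept_ids)
        assert sum(rid.startswith("f_") for rid in kept_ids) >= 27

    def test_empty_read_set(self, make_db):
        kept, removed = subtract_host([], make_db({"h": "123412341234"}),
                                      MatchParams())
        assert kept == [] and removed == 0


class TestCoverage:
    def _hit(self, ref_id, ref_offset, length, read_id="r1"):
        return MatchHit(read_id=read_id, ref_id=ref_id, strand="+",
                        read_offset=0, ref_offset=ref_offset, length=length,
                        mismatches=0, score=length, approx_ref_span=0.0)

    def test_tiling_hits_give_full_coverage(self, make_db):
        db = make_db({"ref1": "1234123412"})
        hits = [self._hit("ref1", 0, 5), self._hit("ref1", 5, 5, read_id="r2")]
        rows = coverage_report(hits, db)
        assert rows[0].coverage_percent == 100.0
        assert rows[0].n_hits == 2 and rows[0].n_reads == 2

    def test_no_hits_zero_coverage(self, make_db):
        rows = coverage_report([], make_db({"a": "123412341", "b": "123412341"}))
        assert all(r.coverage_percent == 0.0 for r in rows)

    def test_half_coverage(self, make_db):
        rows = coverage_report([self._hit("ref1", 2, 5)], make_db({"ref1": "1234123412"}))
        assert rows[0].covered_symbols == 5
        assert rows[0].coverage_percent == 50.0

    def test_overlapping_intervals_counted_once(self, make_db):
        db = make_db({"ref1": "1234123412"})
        hits = [self._hit("ref1", 0, 6), self._hit("ref1", 4, 4)]
        assert coverage_report(hits, db)[0].covered_symbols == 8

    def test_adding_hits_never_decreases_coverage(self, make_db, rng):
        db = make_db({"ref1": "1234123412" * 3})
        hits = []
        prev = 0.0
        for _ in range(10):
            off = int(rng.integers(0, 25))
            hits.append(self._hit("ref1", off, int(rng.integers(1, 6))))
            cov = coverage_report(hits, db)[0].coverage_percent
            assert cov >= prev
            assert 0.0 <= cov <= 100.0
            prev = cov

    def test_unknown_reference_rejected(self, make_db):
        with pytest.raises(InputError):
            coverage_report([self._hit("ghost", 0, 4)], make_db({"ref1": "12341234"}))

    def test_rows_sorted_by_coverage_then_id(self, make_db):
        db = make_db({"low": "1234123412", "high": "1234123412"})
        rows = coverage_report([self._hit("high", 0, 8)], db)
        assert [r.ref_id for r in rows] == ["high", "low"]


class TestMatchRead:
    def test_reverse_strand_read_matches(self, make_seq_db):
        genome = generate_genome(20_000, 0.5, seed=21, record_id="g")
        db = make_seq_db({"g": genome.seq})
        params = MatchParams(tolerance=0, adjacent_free=False)
        index = build_index(db, params)
        reads, truth = simulate_reads(genome, ReadSimParams(n_reads=40, seed=22))
        minus = [r for r, t in zip(reads, truth) if t.strand == "-"]
        assert minus, "expected some minus-strand reads"
        for read in minus[:10]:
            hits = match_read(encode_read(read.id, read.seq, db.profile),
                              index, db, params)
            assert any(h.ref_id == "g" for h in hits)

    def test_sliced_database_queries_try_all_phases(self, make_seq_db):
        profile = EncodingProfile(slice_stride=2)
        genome = generate_genome(40_000, 0.5, seed=23, record_id="g")
        db = make_seq_db({"g": genome.seq}, profile)
        params = MatchParams(seed_len=6, tolerance=0, min_hit_len=8,
                             adjacent_free=False)
        index = build_index(db, params)
        reads, _ = simulate_reads(genome, ReadSimParams(n_reads=30, read_len=300,
                                                        seed=24))
        matched = sum(
            bool(match_read(encode_read(r.id, r.seq, profile), index, db, params))
            for r in reads
        )
        assert matched >= 27  # slicing costs some sensitivity, not much

    def test_multi_channel_intersection(self, make_seq_db):
        profile = EncodingProfile(channels=("A", "C"))
        genome = generate_genome(20_000, 0.5, seed=25, record_id="g")
        db = make_seq_db({"g": genome.seq}, profile)
        params = MatchParams(tolerance=0, adjacent_free=False)
        index = build_index(db, params)
        reads, _ = simulate_reads(genome, ReadSimParams(n_reads=10, seed=26))
        for r in reads:
            hits = match_read(encode_read(r.id, r.seq, profile), index, db, params)
            assert any(h.ref_id == "g" for h in hits)
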