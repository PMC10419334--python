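"""Approximate matching of reads to references in wave-identity space.

The matcher is a *prefilter*: it finds candidate subject references for
each read by comparing their lossy identity codes, symbol by symbol, so
that an expensive nucleotide-level aligner only needs to look at the
survivors.  Matching is seed-and-extend over the identity alphabet: exact
k-symbol seeds are looked up in a postings index, then each seeded
diagonal is scanned for maximal windows whose mismatch count stays within
a tolerance.  A mismatch between bin symbols of *adjacent rank* can be
made free, which absorbs the typical effect of a small indel (the gap
moves to a neighbouring bin).

A brute-force oracle (:func:`brute_force_matches`) scans every diagonal
without seeding and is used to validate the indexed path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, InputError
from .wave_codec import (
    EncodingProfile,
    WaveIdentity,
    encode_sequence,
    estimate_span,
    reverse_complement,
)

__all__ = [
    "MatchParams",
    "IdentityIndex",
    "MatchHit",
    "CoverageRow",
    "build_index",
    "find_matches",
    "brute_force_matches",
    "encode_read",
    "match_read",
    "subtract_host",
    "coverage_report",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MatchParams:
    """Knobs of the identity matcher.

    seed_len
        Exact-seed length k in symbols.
    tolerance
        Maximum number of costed symbol mismatches per hit.
    adjacent_free
        When true, a mismatch between bin symbols of adjacent rank costs
        nothing (indel tolerance).
    min_hit_len
        Minimum hit length in symbols.
    max_hits_per_read
        Cap on reported hits per read after score sorting.
    require_full_read
        Containment mode: only report hits spanning the read's entire
        identity.  Appropriate for error-free validation reads, where the
        whole identity must occur in the source reference.
    """

    seed_len: int = 8
    tolerance: int = 2
    adjacent_free: bool = True
    min_hit_len: int = 12
    max_hits_per_read: int = 100
    require_full_read: bool = False

    def __post_init__(self) -> None:
        if self.seed_len < 1:
            raise InputError("seed_len must be >= 1")
        if self.tolerance < 0:
            raise InputError("tolerance must be >= 0")
        if self.min_hit_len < self.seed_len:
            raise InputError("min_hit_len must be >= seed_len")


@dataclass
class IdentityIndex:
    """Postings from k-symbol substrings to (reference id, raw-code offset)."""

    k: int
    postings: dict[str, list[tuple[str, int]]] = field(default_factory=dict)
    raw_codes: dict[str, str] = field(default_factory=dict)
    rank_arrays: dict[str, np.ndarray] = field(default_factory=dict)
    profile_id: str = ""


@dataclass
class MatchHit:
    """One read-to-reference hit in identity coordinate space."""

    read_id: str
    ref_id: str
    strand: str
    read_offset: int
    ref_offset: int
    length: int
    mismatches: int
    score: int
    approx_ref_span: float
    channel: str = "A"


def _rank_array(code: str, profile: EncodingProfile) -> np.ndarray:
    table = profile.bin_table
    lut = np.full(128, -1, dtype=np.int16)
    for sym in table.symbols:
        lut[ord(sym)] = table.rank(sym)
    ranks = lut[np.frombuffer(code.encode("ascii"), dtype=np.uint8)]
    if (ranks < 0).any():
        raise InputError("raw code contains symbols outside the bin table")
    return ranks


def build_index(db, params: MatchParams) -> IdentityIndex:
    """Index every k-substring of every raw reference identity.

    References shorter than k symbols are skipped with a warning.  Indexing
    is over the *primary* channel (the profile's first); additional
    channels are re-scanned on demand by :func:`match_read`.
    """
    profile = db.profile
    index = IdentityIndex(k=params.seed_len, profile_id=profile.profile_id)
    channel = profile.channels[0]
    for record in db.records:
        raw = record.identities[channel].raw_code()
        index.raw_codes[record.ref_id] = raw
        index.rank_arrays[record.ref_id] = _rank_array(raw, profile)
        if len(raw) < params.seed_len:
            logger.warning(
                "reference %s identity has %d symbols (< k=%d); skipped",
                record.ref_id, len(raw), params.seed_len,
            )
            continue
        for off in range(len(raw) - params.seed_len + 1):
            index.postings.setdefault(raw[off:off + params.seed_len], []).append(
                (record.ref_id, off)
            )
    return index


def _mismatch_costs(
    read_ranks: np.ndarray, ref_ranks: np.ndarray, adjacent_free: bool
) -> np.ndarray:
    diff = np.abs(read_ranks - ref_ranks)
    if adjacent_free:
        return (diff > 1).astype(np.int64)
    return (diff > 0).astype(np.int64)


def _maximal_windows(costs: np.ndarray, tolerance: int) -> list[tuple[int, int, int]]:
    """All maximal windows of *costs* whose sum is <= tolerance.

    Returns (start, end, mismatches) triples, end exclusive.  A window is
    maximal when it cannot be extended in either direction.  Uses the
    standard two-pointer sweep: e(s), the furthest end for start s, is
    non-decreasing, and the window at s is maximal iff e(s) strictly grew.
    """
    n = len(costs)
    windows: list[tuple[int, int, int]] = []
    e = 0
    budget = 0  # sum of costs[s:e]
    prev_e = -1
    for s in range(n):
        if e < s:
            e = s
            budget = 0
        while e < n and budget + int(costs[e]) <= tolerance:
            budget += int(costs[e])
            e += 1
        if e > s and e > prev_e:
            windows.append((s, e, budget))
            prev_e = e
        if e > s:
            budget -= int(costs[s])
    return windows


def _hits_on_diagonal(
    read_raw: str,
    ref_raw: str,
    diag: int,
    read_ranks: np.ndarray,
    ref_ranks: np.ndarray,
    params: MatchParams,
    seed_starts: set[int] | None,
) -> list[tuple[int, int, int, int]]:
    """Maximal qualifying windows on one diagonal (diag = ref_off - read_off).

    Returns (read_offset, ref_offset, length, mismatches).  When
    *seed_starts* is given (indexed path) only windows containing at least
    one seed occurrence are kept, which is what guarantees the indexed
    result is a subset of the brute-force one.
    """
    r0 = max(0, -diag)
    r1 = min(len(read_raw), len(ref_raw) - diag)
    if r1 - r0 < params.min_hit_len:
        return []
    costs = _mismatch_costs(
        read_ranks[r0:r1], ref_ranks[r0 + diag:r1 + diag], params.adjacent_free
    )
    out = []
    for s, e, mism in _maximal_windows(costs, params.tolerance):
        length = e - s
        if length < params.min_hit_len:
            continue
        read_off = r0 + s
        if seed_starts is not None and not any(
            read_off <= p and p + params.seed_len <= read_off + length
            for p in seed_starts
        ):
            continue
        out.append((read_off, read_off + diag, length, mism))
    return out


def _merge_and_rank(
    raw_hits: list[MatchHit], params: MatchParams
) -> list[MatchHit]:
    """Merge overlapping hits per (read, ref, strand) keeping the longest,
    then sort by score descending with (ref_id, ref_offset) tie-break and
    cap at max_hits_per_read."""
    groups: dict[tuple[str, str, str, str], list[MatchHit]] = {}
    for h in raw_hits:
        groups.setdefault((h.read_id, h.ref_id, h.strand, h.channel), []).append(h)
    merged: list[MatchHit] = []
    for hits in groups.values():
        hits.sort(key=lambda h: (h.ref_offset, -h.length))
        cluster: list[MatchHit] = []
        cluster_end = -1
        for h in hits:
            if cluster and h.ref_offset < cluster_end:
                cluster.append(h)
                cluster_end = max(cluster_end, h.ref_offset + h.length)
            else:
                if cluster:
                    merged.append(max(cluster, key=lambda c: (c.length, c.score, -c.ref_offset)))
                cluster = [h]
                cluster_end = h.ref_offset + h.length
        if cluster:
            merged.append(max(cluster, key=lambda c: (c.length, c.score, -c.ref_offset)))
    merged.sort(key=lambda h: (-h.score, h.ref_id, h.ref_offset))
    return merged[: params.max_hits_per_read]


def _check_profiles(identity: WaveIdentity, db) -> None:
    if identity.profile_id != db.profile.profile_id:
        raise ConfigError(
            "read identity was encoded under a different profile than the "
            f"database ({identity.profile_id!r} vs {db.profile.profile_id!r})"
        )


def _make_hit(
    read_id: str, ref_id: str, strand: str, channel: str,
    read_off: int, ref_off: int, length: int, mism: int,
    ref_raw: str, profile: EncodingProfile,
) -> MatchHit:
    return MatchHit(
        read_id=read_id, ref_id=ref_id, strand=strand,
        read_offset=read_off, ref_offset=ref_off,
        length=length, mismatches=mism,
        score=length - 2 * mism,
        approx_ref_span=estimate_span(
            ref_raw[ref_off:ref_off + length], profile.bin_table
        ),
        channel=channel,
    )


def find_matches(
    read_identity: WaveIdentity,
    index: IdentityIndex,
    db,
    params: MatchParams,
    read_id: str = "read",
    strand: str = "+",
    merge: bool = True,
) -> list[MatchHit]:
    """Seed-and-extend matching of one read identity against the index.

    Every diagonal holding at least one exact k-seed is scanned for maximal
    mismatch-bounded windows; windows must contain a seed, reach
    ``min_hit_len`` and stay within ``tolerance``.  With ``merge`` (the
    default), overlapping hits per (read, reference, strand) are merged to
    the longest and results are score sorted and capped; ``merge=False``
    returns the raw maximal windows, which are always a subset of the
    brute-force oracle's.
    """
    _check_profiles(read_identity, db)
    read_raw = read_identity.raw_code()
    k = params.seed_len
    if len(read_raw) < k:
        return []
    profile = db.profile
    read_ranks = _rank_array(read_raw, profile)
    # group seed occurrences by (ref, diagonal)
    seeds: dict[tuple[str, int], set[int]] = {}
    for read_off in range(len(read_raw) - k + 1):
        for ref_id, ref_off in index.postings.get(read_raw[read_off:read_off + k], ()):
            seeds.setdefault((ref_id, ref_off - read_off), set()).add(read_off)
    raw_hits: list[MatchHit] = []
    ranks_cache = index.rank_arrays
    for (ref_id, diag), starts in seeds.items():
        ref_raw = index.raw_codes[ref_id]
        if ref_id not in ranks_cache:
            ranks_cache[ref_id] = _rank_array(ref_raw, profile)
        for read_off, ref_off, length, mism in _hits_on_diagonal(
            read_raw, ref_raw, diag, read_ranks, ranks_cache[ref_id], params, starts
        ):
            if params.require_full_read and (read_off != 0 or length != len(read_raw)):
                continue
            raw_hits.append(_make_hit(
                read_id, ref_id, strand, read_identity.channel,
                read_off, ref_off, length, mism, ref_raw, profile,
            ))
    if not merge:
        raw_hits.sort(key=lambda h: (h.ref_id, h.ref_offset, h.read_offset))
        return raw_hits
    return _merge_and_rank(raw_hits, params)


def brute_force_matches(
    read_identity: WaveIdentity,
    db,
    params: MatchParams,
    read_id: str = "read",
    strand: str = "+",
    merge: bool = True,
) -> list[MatchHit]:
    """Oracle: scan every diagonal of every reference, no seeding.

    Applies the same window, merging and ranking rules as
    :func:`find_matches`; on inputs where every qualifying window contains
    an exact k-seed the two are identical.
    """
    _check_profiles(read_identity, db)
    read_raw = read_identity.raw_code()
    if len(read_raw) < params.min_hit_len:
        return []
    profile = db.profile
    read_ranks = _rank_array(read_raw, profile)
    channel = read_identity.channel
    raw_hits: list[MatchHit] = []
    for record in db.records:
        ref_raw = record.identities[channel].raw_code()
        if len(ref_raw) < params.min_hit_len:
            continue
        ref_ranks = _rank_array(ref_raw, profile)
        for diag in range(-(len(read_raw) - params.min_hit_len),
                          len(ref_raw) - params.min_hit_len + 1):
            for read_off, ref_off, length, mism in _hits_on_diagonal(
                read_raw, ref_raw, diag, read_ranks, ref_ranks, params, None
            ):
                if params.require_full_read and (read_off != 0 or length != len(read_raw)):
                    continue
                raw_hits.append(_make_hit(
                    read_id, record.ref_id, strand, channel,
                    read_off, ref_off, length, mism, ref_raw, profile,
                ))
    if not merge:
        raw_hits.sort(key=lambda h: (h.ref_id, h.ref_offset, h.read_offset))
        return raw_hits
    return _merge_and_rank(raw_hits, params)


@dataclass
class EncodedRead:
    """Per-strand, per-phase, per-channel identities of one read."""

    read_id: str
    # (strand, phase) -> {channel: WaveIdentity}
    identities: dict[tuple[str, int], dict[str, WaveIdentity]]


def encode_read(read_id: str, seq: str, profile: EncodingProfile) -> EncodedRead:
    """Encode a read on both strands and, for sliced profiles, all phases."""
    identities: dict[tuple[str, int], dict[str, WaveIdentity]] = {}
    for strand, s in (("+", seq), ("-", reverse_complement(seq))):
        for phase in range(profile.slice_stride):
            identities[(strand, phase)] = encode_sequence(s, profile, phase=phase)
    return EncodedRead(read_id=read_id, identities=identities)


def match_read(
    encoded: EncodedRead,
    index: IdentityIndex,
    db,
    params: MatchParams,
) -> list[MatchHit]:
    """Match one encoded read: union over strands and slice phases,
    intersection over channels (a reference is reported only when every
    channel produced a hit for it)."""
    profile = db.profile
    primary = profile.channels[0]
    all_hits: list[MatchHit] = []
    for (strand, _phase), chans in encoded.identities.items():
        all_hits.extend(find_matches(
            chans[primary], index, db, params,
            read_id=encoded.read_id, strand=strand,
        ))
    if len(profile.channels) > 1:
        keep: set[str] | None = {h.ref_id for h in all_hits}
        for channel in profile.channels[1:]:
            chan_refs: set[str] = set()
            for (strand, _phase), chans in encoded.identities.items():
                for h in brute_force_matches(
                    chans[channel], db, params,
                    read_id=encoded.read_id, strand=strand,
                ):
                    chan_refs.add(h.ref_id)
            keep &= chan_refs
        all_hits = [h for h in all_hits if h.ref_id in keep]
    return _merge_and_rank(all_hits, params)


def subtract_host(
    encoded_reads: list[EncodedRead],
    host_db,
    params: MatchParams,
    host_index: IdentityIndex | None = None,
) -> tuple[list[EncodedRead], int]:
    """Remove reads with at least one hit against the host database."""
    if host_index is None:
        host_index = build_index(host_db, params)
    kept: list[EncodedRead] = []
    removed = 0
    for enc in encoded_reads:
        if match_read(enc, host_index, host_db, params):
            removed += 1
        else:
            kept.append(enc)
    return kept, removed


@dataclass
class CoverageRow:
    ref_id: str
    covered_symbols: int
    total_symbols: int
    coverage_percent: float
    n_hits: int
    n_reads: int


def coverage_report(hits: list[MatchHit], db) -> list[CoverageRow]:
    """Per-reference coverage of the raw identity by the union of hit intervals.

    Only primary-channel hits contribute (offsets of other channels live in
    a different coordinate space).  Rows are sorted by coverage descending,
    then reference id.
    """
    primary = db.profile.channels[0]
    by_ref: dict[str, list[MatchHit]] = {r.ref_id: [] for r in db.records}
    for h in hits:
        if h.ref_id not in by_ref:
            raise InputError(f"hit references unknown id {h.ref_id!r}")
        if h.channel == primary:
            by_ref[h.ref_id].append(h)
    rows: list[CoverageRow] = []
    for record in db.records:
        total = len(record.identities[primary].raw_code())
        ref_hits = by_ref[record.ref_id]
        intervals = sorted((h.ref_offset, h.ref_offset + h.length) for h in ref_hits)
        covered = 0
        cur_start, cur_end = None, None
        for start, end in intervals:
            if cur_end is None or start > cur_end:
                if cur_end is not None:
                    covered += cur_end - cur_start
                cur_start, cur_end = start, end
            else:
                cur_end = max(cur_end, end)
        if cur_end is not None:
            covered += cur_end - cur_start
        covered = min(covered, total)
        rows.append(CoverageRow(
            ref_id=record.ref_id,
            covered_symbols=covered,
            total_symbols=total,
            coverage_percent=100.0 * covered / total if total else 0.0,
            n_hits=len(ref_hits),
            n_reads=len({h.read_id for h in ref_hits}),
        ))
    rows.sort(key=lambda r: (-r.coverage_percent, r.ref_id))
    return rows
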