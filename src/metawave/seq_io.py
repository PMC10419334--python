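"""Sequence I/O, pre-alignment filters and the MGDB database format.

FASTA/FASTQ parsing is delegated to Biopython (gzip-aware by file suffix).
MGDB is this package's on-disk form of a compressed reference database.
It has two dialects:

* **text** — line 1 is ``#MGDB1<TAB><profile block>``; each identity is a
  ``>ref_id<TAB>source_length<TAB>channel`` header line followed by the
  code line.  Diff-able, meant for debugging.
* **packed** — magic ``MGDB`` + version byte 0x01, a little-endian u16
  profile-block length plus the block, then per identity: id length (u8),
  id bytes, source_length (u32 LE), symbol count (u32 LE) and
  ``ceil(5n/8)`` bytes of 5-bit packed symbols.  For multi-channel
  profiles a record's identities are emitted consecutively in profile
  channel order, so the channel is implied by position.

Both dialects round-trip bit-exactly.
"""

from __future__ import annotations

import gzip
import math
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

from .errors import FormatError, InputError
from .wave_codec import (
    EncodingProfile,
    WaveIdentity,
    encode_sequence,
    pack_symbols,
    unpack_symbols,
)

__all__ = [
    "SeqRecord",
    "QCParams",
    "DbRecord",
    "CompressedDatabase",
    "read_fasta",
    "read_fastq",
    "write_fasta",
    "write_fastq",
    "qc_filter",
    "write_db",
    "read_db",
    "compress_fasta",
    "compression_stats",
]

MGDB_MAGIC = b"MGDB"
MGDB_VERSION = 1


@dataclass
class SeqRecord:
    """A sequence with optional per-base Phred qualities."""

    id: str
    seq: str
    qual: list[int] | None = None

    def __post_init__(self) -> None:
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise FormatError(
                f"record {self.id!r}: quality length {len(self.qual)} != "
                f"sequence length {len(self.seq)}"
            )


@dataclass(frozen=True)
class QCParams:
    """Read quality-control thresholds (FASTA records skip quality rules)."""

    min_mean_quality: float = 20.0
    min_length: int = 50
    dedup: bool = True
    trim_n_edges: bool = True

    def __post_init__(self) -> None:
        if self.min_mean_quality < 0 or self.min_length < 0:
            raise InputError("QC thresholds must be non-negative")


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(path: str | Path) -> Iterator[SeqRecord]:
    """Stream records from a (possibly gzipped) FASTA file."""
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            yield SeqRecord(id=rec.id, seq=str(rec.seq).upper())


def read_fastq(path: str | Path) -> Iterator[SeqRecord]:
    """Stream records from a (possibly gzipped) Phred+33 FASTQ file."""
    with _open_text(path) as handle:
        try:
            for rec in SeqIO.parse(handle, "fastq"):
                yield SeqRecord(
                    id=rec.id,
                    seq=str(rec.seq).upper(),
                    qual=list(rec.letter_annotations["phred_quality"]),
                )
        except ValueError as exc:  # Biopython names the offending record
            raise FormatError(str(exc)) from exc


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "wt") as out:
        for rec in records:
            out.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                out.write(rec.seq[i:i + width] + "\n")
            if not rec.seq:
                out.write("\n")


def write_fastq(records: Iterable[SeqRecord], path: str | Path) -> None:
    with open(path, "wt") as out:
        for rec in records:
            qual = rec.qual if rec.qual is not None else [30] * len(rec.seq)
            out.write(
                f"@{rec.id}\n{rec.seq}\n+\n"
                + "".join(chr(q + 33) for q in qual) + "\n"
            )


def qc_filter(
    records: Iterable[SeqRecord], params: QCParams | None = None
) -> tuple[list[SeqRecord], dict[str, int]]:
    """Apply edge-N trimming, length, mean-quality and duplicate filters.

    Returns the surviving records plus per-rule drop counts.  Rules apply
    in the order trim -> length -> quality -> dedup, so each record is
    counted under the first rule that rejects it.
    """
    params = params or QCParams()
    kept: list[SeqRecord] = []
    seen: set[str] = set()
    summary = {"input": 0, "kept": 0, "low_quality": 0, "short": 0, "duplicate": 0}
    for rec in records:
        summary["input"] += 1
        seq, qual = rec.seq, rec.qual
        if params.trim_n_edges:
            start = len(seq) - len(seq.lstrip("Nn"))
            end = len(seq) - (len(seq) - len(seq.rstrip("Nn")))
            seq = seq[start:end]
            if qual is not None:
                qual = qual[start:end]
        if len(seq) < params.min_length:
            summary["short"] += 1
            continue
        if qual is not None and sum(qual) / len(qual) < params.min_mean_quality:
            summary["low_quality"] += 1
            continue
        if params.dedup:
            if seq in seen:
                summary["duplicate"] += 1
                continue
            seen.add(seq)
        kept.append(SeqRecord(id=rec.id, seq=seq, qual=qual))
        summary["kept"] += 1
    return kept, summary


@dataclass
class DbRecord:
    ref_id: str
    source_length: int
    identities: dict[str, WaveIdentity]


@dataclass
class CompressedDatabase:
    """A set of reference wave identities sharing one encoding profile."""

    profile: EncodingProfile
    records: list[DbRecord] = field(default_factory=list)
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.ref_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise InputError("duplicate ref_ids in database")
        for rec in self.records:
            for ident in rec.identities.values():
                if ident.profile_id != self.profile.profile_id:
                    raise InputError(
                        f"record {rec.ref_id!r} was encoded under a different profile"
                    )

    def __len__(self) -> int:
        return len(self.records)

    def get(self, ref_id: str) -> DbRecord:
        for rec in self.records:
            if rec.ref_id == ref_id:
                return rec
        raise KeyError(ref_id)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, CompressedDatabase)
            and self.profile.profile_id == other.profile.profile_id
            and self.records == other.records
        )


def write_db(db: CompressedDatabase, path: str | Path, packed: bool | None = None) -> None:
    """Write a database in the packed (default) or text MGDB dialect."""
    if packed is None:
        packed = db.profile.packed
    profile_block = db.profile.profile_id
    if packed:
        with open(path, "wb") as out:
            out.write(MGDB_MAGIC + bytes([MGDB_VERSION]))
            block = profile_block.encode("ascii")
            out.write(struct.pack("<H", len(block)) + block)
            for rec in db.records:
                for channel in db.profile.channels:
                    ident = rec.identities[channel]
                    rid = rec.ref_id.encode("utf-8")
                    if len(rid) > 255:
                        raise InputError(f"ref_id too long: {rec.ref_id!r}")
                    out.write(bytes([len(rid)]) + rid)
                    out.write(struct.pack("<II", rec.source_length, len(ident.code)))
                    out.write(pack_symbols(ident.code))
    else:
        with open(path, "wt") as out:
            out.write(f"#MGDB1\t{profile_block}\n")
            for rec in db.records:
                for channel in db.profile.channels:
                    ident = rec.identities[channel]
                    out.write(f">{rec.ref_id}\t{rec.source_length}\t{channel}\n")
                    out.write(ident.code + "\n")


def _read_exact(handle, n: int, what: str) -> bytes:
    data = handle.read(n)
    if len(data) != n:
        raise FormatError(
            f"truncated MGDB file: expected {n} bytes for {what} "
            f"at offset {handle.tell() - len(data)}"
        )
    return data


def read_db(path: str | Path) -> CompressedDatabase:
    """Read either MGDB dialect, inverting :func:`write_db` bit-exactly."""
    with open(path, "rb") as probe:
        head = probe.read(6)
    if head[:4] == MGDB_MAGIC:
        if len(head) < 5 or head[4] != MGDB_VERSION:
            raise FormatError("unsupported or truncated MGDB version byte at offset 4")
        return _read_db_packed(path)
    if head.startswith(b"#MGDB1"):
        return _read_db_text(path)
    raise FormatError("bad magic at offset 0: not an MGDB file")


def _read_db_packed(path: str | Path) -> CompressedDatabase:
    with open(path, "rb") as handle:
        _read_exact(handle, 5, "magic")
        (block_len,) = struct.unpack("<H", _read_exact(handle, 2, "profile length"))
        profile = EncodingProfile.from_profile_id(
            _read_exact(handle, block_len, "profile block").decode("ascii")
        )
        by_id: dict[str, DbRecord] = {}
        order: list[str] = []
        pending: dict[str, int] = {}
        while True:
            first = handle.read(1)
            if not first:
                break
            rid_len = first[0]
            rid = _read_exact(handle, rid_len, "ref id").decode("utf-8")
            source_length, n_symbols = struct.unpack(
                "<II", _read_exact(handle, 8, "record header")
            )
            payload = _read_exact(handle, math.ceil(5 * n_symbols / 8), "payload")
            code = unpack_symbols(payload, n_symbols)
            if rid not in by_id:
                by_id[rid] = DbRecord(rid, source_length, {})
                order.append(rid)
                pending[rid] = 0
            channel = profile.channels[pending[rid]]
            pending[rid] += 1
            by_id[rid].identities[channel] = WaveIdentity(
                channel=channel, code=code,
                source_length=source_length, profile_id=profile.profile_id,
            )
        return CompressedDatabase(profile, [by_id[r] for r in order])


def _read_db_text(path: str | Path) -> CompressedDatabase:
    with open(path, "rt") as handle:
        header = handle.readline().rstrip("\n")
        tag, _, profile_block = header.partition("\t")
        if tag != "#MGDB1" or not profile_block:
            raise FormatError("malformed MGDB text header at offset 0")
        profile = EncodingProfile.from_profile_id(profile_block)
        by_id: dict[str, DbRecord] = {}
        order: list[str] = []
        for line in handle:
            line = line.rstrip("\n")
            if not line.startswith(">"):
                raise FormatError(f"expected record header, got {line[:30]!r}")
            try:
                rid, length_s, channel = line[1:].split("\t")
                source_length = int(length_s)
            except ValueError as exc:
                raise FormatError(f"malformed record header {line!r}") from exc
            code = handle.readline().rstrip("\n")
            if rid not in by_id:
                by_id[rid] = DbRecord(rid, source_length, {})
                order.append(rid)
            by_id[rid].identities[channel] = WaveIdentity(
                channel=channel, code=code,
                source_length=source_length, profile_id=profile.profile_id,
            )
        return CompressedDatabase(profile, [by_id[r] for r in order])


def compress_fasta(
    path: str | Path, profile: EncodingProfile | None = None
) -> CompressedDatabase:
    """Encode every FASTA record into a compressed database."""
    profile = profile or EncodingProfile()
    records = [
        DbRecord(rec.id, len(rec.seq), encode_sequence(rec.seq, profile))
        for rec in read_fasta(path)
    ]
    return CompressedDatabase(profile, records, provenance={"source": str(path)})


def compression_stats(db: CompressedDatabase) -> tuple[int, int, int]:
    """(original bytes, compressed bytes, shrink %).

    Original counts nucleotide letters only; compressed counts the packed
    5-bit record payloads (headers and delimiters excluded).  Shrink % is
    ``100 * (1 - compressed/original)`` rounded to the nearest integer.
    """
    original = sum(rec.source_length for rec in db.records)
    compressed = sum(
        math.ceil(5 * len(ident.code) / 8)
        for rec in db.records
        for ident in rec.identities.values()
    )
    shrink = round(100 * (1 - compressed / original)) if original else 0
    return original, compressed, shrink
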