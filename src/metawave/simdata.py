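"""Synthetic genomes and short reads with explicit mutation models.

The simulator exists so the whole pipeline — compression, QC, host
subtraction, matching, coverage — can be exercised end to end on data
whose truth is known.  Substitutions are split into transitions (A⇋G,
C⇋T) and transversions; indels have geometric lengths; base qualities
are drawn from a truncated normal on the Phred scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError
from .seq_io import SeqRecord
from .wave_codec import reverse_complement

__all__ = [
    "MutationModel",
    "ReadSimParams",
    "MutationEvent",
    "TruthEntry",
    "generate_genome",
    "mutate",
    "simulate_reads",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


@dataclass(frozen=True)
class MutationModel:
    """Per-base substitution/indel probabilities.

    ``ts_fraction`` is the fraction of substitutions that are transitions
    (default 2/3, reflecting the commonly observed excess of transitions
    over the 1/3 expected from pathway counting alone).  Indel lengths are
    geometric with mean ``indel_len``.
    """

    subst_rate: float = 0.0
    ts_fraction: float = 2 / 3
    indel_rate: float = 0.0
    indel_len: float = 1.5
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("subst_rate", "ts_fraction", "indel_rate"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise InputError(f"{name} must lie in [0, 1], got {value}")
        if self.indel_len < 1.0:
            raise InputError("indel_len (geometric mean length) must be >= 1")


@dataclass(frozen=True)
class ReadSimParams:
    """Short-read simulation parameters (read_len default 150 nt)."""

    n_reads: int = 1000
    read_len: int = 150
    error_model: MutationModel = field(default_factory=MutationModel)
    qual_mean: float = 35.0
    qual_sd: float = 3.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.read_len < 1:
            raise InputError("read_len must be >= 1")
        if self.n_reads < 0:
            raise InputError("n_reads must be >= 0")


@dataclass
class MutationEvent:
    position: int  # 0-based position in the input sequence
    type: str  # "subst" | "ins" | "del"
    before: str
    after: str


@dataclass
class TruthEntry:
    read_id: str
    ref_id: str
    start: int  # 0-based, half-open interval on the reference
    end: int
    strand: str
    n_subst: int
    n_indel: int


def generate_genome(
    length: int, gc_content: float = 0.5, seed: int | None = None,
    record_id: str = "genome",
) -> SeqRecord:
    """I.i.d. random genome with P(G)=P(C)=gc/2, P(A)=P(T)=(1-gc)/2."""
    if length < 0:
        raise InputError("length must be >= 0")
    if not 0.0 <= gc_content <= 1.0:
        raise InputError("gc_content must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    at = (1 - gc_content) / 2
    probs = [at, gc_content / 2, gc_content / 2, at]
    seq = rng.choice(_BASES, size=length, p=probs).tobytes().decode("ascii")
    return SeqRecord(id=record_id, seq=seq)


def mutate(
    seq: str,
    model: MutationModel,
    rng: np.random.Generator | None = None,
) -> tuple[str, list[MutationEvent]]:
    """Apply the mutation model to a sequence, returning the event log.

    Each base is substituted with probability ``subst_rate``; a
    substitution is a transition with probability ``ts_fraction``, else a
    uniformly chosen transversion partner.  Before each position an indel
    fires with probability ``indel_rate`` (insertion or deletion, equally
    likely) with geometric length.
    """
    if rng is None:
        rng = np.random.default_rng(model.seed)
    n = len(seq)
    events: list[MutationEvent] = []
    if n == 0:
        return seq, events

    bases = list(seq)
    if model.subst_rate > 0:
        hits = np.flatnonzero(rng.random(n) < model.subst_rate)
        is_ts = rng.random(len(hits)) < model.ts_fraction
        choices = rng.integers(0, 2, size=len(hits))
        for pos, ts, pick in zip(hits, is_ts, choices):
            before = bases[pos]
            if before not in _TRANSITION:  # leave N untouched
                continue
            after = _TRANSITION[before] if ts else _TRANSVERSIONS[before][pick]
            bases[pos] = after
            events.append(MutationEvent(int(pos), "subst", before, after))

    if model.indel_rate > 0:
        p_geom = 1.0 / model.indel_len
        sites = np.flatnonzero(rng.random(n) < model.indel_rate)
        is_ins = rng.random(len(sites)) < 0.5
        # splice from the right so earlier positions stay valid
        for pos, ins in list(zip(sites, is_ins))[::-1]:
            length = int(rng.geometric(p_geom))
            if ins:
                insert = rng.choice(_BASES, size=length).tobytes().decode("ascii")
                bases[pos:pos] = list(insert)
                events.append(MutationEvent(int(pos), "ins", "", insert))
            else:
                removed = "".join(bases[pos:pos + length])
                del bases[pos:pos + length]
                events.append(MutationEvent(int(pos), "del", removed, ""))
        events.sort(key=lambda e: e.position)

    return "".join(bases), events


def simulate_reads(
    genome: SeqRecord, params: ReadSimParams
) -> tuple[list[SeqRecord], list[TruthEntry]]:
    """Sample uniform-start reads from either strand with sequencing error.

    Returns FASTQ-ready records and a truth table of source intervals.
    Deterministic for a fixed seed.
    """
    if params.n_reads > 0 and len(genome.seq) < params.read_len:
        raise InputError(
            f"genome length {len(genome.seq)} shorter than read_len {params.read_len}"
        )
    rng = np.random.default_rng(params.seed)
    reads: list[SeqRecord] = []
    truth: list[TruthEntry] = []
    n_starts = len(genome.seq) - params.read_len + 1
    for i in range(params.n_reads):
        start = int(rng.integers(0, n_starts))
        end = start + params.read_len
        fragment = genome.seq[start:end]
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            fragment = reverse_complement(fragment)
        seq, events = mutate(fragment, params.error_model, rng)
        n_subst = sum(1 for e in events if e.type == "subst")
        n_indel = sum(1 for e in events if e.type in ("ins", "del"))
        qual = np.clip(
            rng.normal(params.qual_mean, params.qual_sd, size=len(seq)),
            2, 41,
        ).round().astype(int).tolist()
        read_id = f"read{i:05d}"
        reads.append(SeqRecord(id=read_id, seq=seq, qual=qual))
        truth.append(TruthEntry(
            read_id=read_id, ref_id=genome.id, start=start, end=end,
            strand=strand, n_subst=n_subst, n_indel=n_indel,
        ))
    return reads, truth
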