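"""Lossy "wave identity" codec for nucleotide sequences.

A sequence is reduced, per *channel* base (A by default), to the series of
gap distances between consecutive occurrences of that base.  Each distance
is mapped to a one-character symbol by a bin table, repeated symbols are
run-length compressed with lowercase prefixes, and the result can be
stride-sliced and bit-packed (5 bits/symbol).  Small indels move a gap to a
neighbouring bin at worst, and any substitution among the non-channel bases
is invisible, which is what makes the encoding usable as a permissive
prefilter for read-to-reference matching.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import FormatError, InputError

__all__ = [
    "BinTable",
    "RLE_PREFIXES",
    "RLE_LENGTHS",
    "EncodingProfile",
    "GapSeries",
    "WaveIdentity",
    "extract_gap_series",
    "bin_distance",
    "bin_series",
    "rle_compress",
    "rle_decompress",
    "slice_code",
    "encode_sequence",
    "pack_symbols",
    "unpack_symbols",
    "estimate_span",
    "reverse_complement",
    "PACK_ALPHABET",
]

#: Maximum distance the default bin table addresses; larger gaps clamp to
#: the final catch-all bin.
MAX_BINNED_DISTANCE = 9999

_DEFAULT_BIN_ENTRIES: tuple[tuple[int, int, str], ...] = (
    (0, 2, "1"), (3, 4, "2"), (5, 6, "3"), (7, 8, "4"), (9, 10, "5"),
    (11, 12, "6"), (13, 14, "7"), (15, 16, "8"), (17, 18, "9"),
    (19, 20, "A"), (21, 22, "B"), (23, 24, "C"), (25, 26, "D"),
    (27, 28, "E"), (29, 30, "F"), (31, 32, "G"), (33, 34, "H"),
    (35, 36, "I"), (37, 38, "J"), (39, MAX_BINNED_DISTANCE, "Z"),
)

#: Run length -> lowercase RLE prefix.  Length 1 has no prefix; runs longer
#: than 10 are decomposed greedily into 10-blocks plus a remainder block.
RLE_PREFIXES: dict[int, str] = {
    10: "a", 9: "b", 8: "c", 7: "d", 6: "e", 5: "f", 4: "g", 3: "h", 2: "i",
}
RLE_LENGTHS: dict[str, int] = {v: k for k, v in RLE_PREFIXES.items()}

#: Canonical symbol enumeration used by the 5-bit packer.
PACK_ALPHABET = "123456789ABCDEFGHIJZabcdefghi"
_PACK_INDEX = {c: i for i, c in enumerate(PACK_ALPHABET)}


@dataclass(frozen=True)
class BinTable:
    """Ordered distance bins, each mapped to a single-character symbol.

    Entries must tile ``[0, 9999]`` contiguously in ascending order with
    distinct symbols.  A symbol's *rank* is its position in the list; the
    matcher treats adjacent-rank symbols as near-equal.
    """

    entries: tuple[tuple[int, int, str], ...] = _DEFAULT_BIN_ENTRIES

    def __post_init__(self) -> None:
        if not self.entries:
            raise InputError("bin table must have at least one entry")
        expected_lo = 0
        seen: set[str] = set()
        for lo, hi, sym in self.entries:
            if lo != expected_lo or hi < lo:
                raise InputError(
                    f"bin table entries must tile [0, {MAX_BINNED_DISTANCE}] "
                    f"contiguously; got ({lo}, {hi})"
                )
            if len(sym) != 1 or sym in seen or sym in RLE_LENGTHS:
                raise InputError(f"invalid or duplicate bin symbol {sym!r}")
            seen.add(sym)
            expected_lo = hi + 1
        if self.entries[-1][1] != MAX_BINNED_DISTANCE:
            raise InputError(f"bin table must end at {MAX_BINNED_DISTANCE}")
        # cached lookup arrays (object.__setattr__ because frozen)
        object.__setattr__(self, "_los", np.array([e[0] for e in self.entries]))
        object.__setattr__(self, "_symbols", "".join(e[2] for e in self.entries))
        object.__setattr__(self, "_ranks", {e[2]: i for i, e in enumerate(self.entries)})

    @property
    def symbols(self) -> str:
        return self._symbols  # type: ignore[attr-defined]

    def rank(self, symbol: str) -> int:
        try:
            return self._ranks[symbol]  # type: ignore[attr-defined]
        except KeyError:
            raise InputError(f"unknown bin symbol {symbol!r}") from None

    def midpoint(self, symbol: str) -> float:
        lo, hi, _ = self.entries[self.rank(symbol)]
        return (lo + hi) / 2.0

    def is_default(self) -> bool:
        return self.entries == _DEFAULT_BIN_ENTRIES

    def spec_string(self) -> str:
        """Serialize as ``default`` or explicit ``lo-hi:sym`` triples."""
        if self.is_default():
            return "default"
        return ",".join(f"{lo}-{hi}:{sym}" for lo, hi, sym in self.entries)

    @classmethod
    def from_spec_string(cls, text: str) -> "BinTable":
        if text == "default":
            return cls()
        entries = []
        for part in text.split(","):
            rng, _, sym = part.partition(":")
            lo, _, hi = rng.partition("-")
            entries.append((int(lo), int(hi), sym))
        return cls(tuple(entries))


@dataclass(frozen=True)
class EncodingProfile:
    """All parameters of the codec; two identities are only comparable when
    produced under the same profile."""

    channels: tuple[str, ...] = ("A",)
    bin_table: BinTable = field(default_factory=BinTable)
    drop_zero_gaps: bool = True
    max_gap: int | None = None
    use_rle: bool = True
    slice_stride: int = 1
    packed: bool = True

    def __post_init__(self) -> None:
        chans = tuple(c.upper() for c in self.channels)
        if not chans or len(set(chans)) != len(chans):
            raise InputError("channels must be a non-empty set without duplicates")
        for c in chans:
            if c not in "ACGT":
                raise InputError(f"channel must be one of A,C,G,T; got {c!r}")
        object.__setattr__(self, "channels", chans)
        if self.slice_stride < 1:
            raise InputError("slice_stride must be >= 1")
        if self.max_gap is not None and self.max_gap < 1:
            raise InputError("max_gap, when set, must be >= 1")

    @property
    def profile_id(self) -> str:
        """Flat key=value block embedded verbatim in MGDB headers."""
        return (
            f"channels={','.join(self.channels)}"
            f";bins={self.bin_table.spec_string()}"
            f";rle={int(self.use_rle)}"
            f";slice={self.slice_stride}"
            f";zero={'drop' if self.drop_zero_gaps else 'keep'}"
            f";pack={int(self.packed)}"
            f";maxgap={self.max_gap if self.max_gap is not None else 'none'}"
        )

    @classmethod
    def from_profile_id(cls, text: str) -> "EncodingProfile":
        fields: dict[str, str] = {}
        for part in text.strip().split(";"):
            key, _, value = part.partition("=")
            if not key or not value:
                raise FormatError(f"malformed profile field {part!r}")
            fields[key] = value
        try:
            return cls(
                channels=tuple(fields["channels"].split(",")),
                bin_table=BinTable.from_spec_string(fields["bins"]),
                use_rle=bool(int(fields["rle"])),
                slice_stride=int(fields["slice"]),
                drop_zero_gaps=fields["zero"] == "drop",
                packed=bool(int(fields["pack"])),
                max_gap=None if fields.get("maxgap", "none") == "none"
                else int(fields["maxgap"]),
            )
        except (KeyError, ValueError) as exc:
            raise FormatError(f"cannot parse profile block {text!r}: {exc}") from exc

    def with_(self, **kwargs) -> "EncodingProfile":
        return replace(self, **kwargs)


@dataclass
class GapSeries:
    """Distances between consecutive channel-base occurrences."""

    channel: str
    gaps: np.ndarray  # int array, every value >= 0

    def __len__(self) -> int:
        return len(self.gaps)


@dataclass
class WaveIdentity:
    """Encoded symbol string for one sequence and one channel."""

    channel: str
    code: str
    source_length: int
    profile_id: str

    def raw_code(self) -> str:
        """Decompressed (RLE-expanded) code."""
        return rle_decompress(self.code) if any(c in RLE_LENGTHS for c in self.code) else self.code


_SEQ_TRANSLATE = bytes.maketrans(b"acgtn", b"ACGTN")
_COMPLEMENT = bytes.maketrans(b"ACGTNacgtn", b"TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.encode("ascii").translate(_COMPLEMENT)[::-1].decode("ascii")


def _seq_to_array(seq: str) -> np.ndarray:
    data = seq.encode("ascii", errors="replace").translate(_SEQ_TRANSLATE)
    arr = np.frombuffer(data, dtype=np.uint8)
    valid = np.isin(arr, np.frombuffer(b"ACGTN", dtype=np.uint8))
    if not valid.all():
        offset = int(np.flatnonzero(~valid)[0])
        raise InputError(
            f"non-IUPAC character {seq[offset]!r} at offset {offset}"
        )
    return arr


def extract_gap_series(
    seq: str, channel: str, profile: EncodingProfile
) -> GapSeries:
    """Count bases strictly between consecutive occurrences of *channel*.

    ``N`` never counts as a channel base but does contribute to distances.
    With fewer than two channel occurrences the series is empty.  Zero gaps
    are removed when the profile says so; gaps above ``max_gap`` (when set)
    are removed as well.
    """
    channel = channel.upper()
    arr = _seq_to_array(seq)
    positions = np.flatnonzero(arr == ord(channel))
    if len(positions) < 2:
        return GapSeries(channel, np.empty(0, dtype=np.int64))
    gaps = np.diff(positions) - 1
    if profile.drop_zero_gaps:
        gaps = gaps[gaps > 0]
    if profile.max_gap is not None:
        gaps = gaps[gaps <= profile.max_gap]
    return GapSeries(channel, gaps)


def bin_distance(d: int, table: BinTable | None = None) -> str:
    """Map one gap distance to its bin symbol; d > 9999 clamps to the last bin."""
    if d < 0:
        raise InputError(f"distance must be non-negative, got {d}")
    table = table or BinTable()
    los = table._los  # type: ignore[attr-defined]
    idx = int(np.searchsorted(los, min(d, MAX_BINNED_DISTANCE), side="right")) - 1
    return table.entries[idx][2]


def bin_series(gaps: GapSeries | np.ndarray, table: BinTable | None = None) -> str:
    """Vectorized bin lookup; output character i encodes gaps[i]."""
    table = table or BinTable()
    values = gaps.gaps if isinstance(gaps, GapSeries) else np.asarray(gaps)
    if len(values) == 0:
        return ""
    if (values < 0).any():
        raise InputError("gap distances must be non-negative")
    clipped = np.minimum(values, MAX_BINNED_DISTANCE)
    idx = np.searchsorted(table._los, clipped, side="right") - 1  # type: ignore[attr-defined]
    syms = np.frombuffer(table.symbols.encode("ascii"), dtype=np.uint8)
    return syms[idx].tobytes().decode("ascii")


def rle_compress(code: str, table: dict[int, str] | None = None) -> str:
    """Run-length compress repeated bin symbols with lowercase prefixes.

    Runs of length 2..10 become ``prefix + symbol``; longer runs decompose
    greedily into 10-blocks first, then one remainder block (a remainder of
    1 is emitted bare).  Output is never longer than input.
    """
    prefixes = table or RLE_PREFIXES
    out: list[str] = []
    i, n = 0, len(code)
    while i < n:
        sym = code[i]
        if sym in RLE_LENGTHS:
            raise InputError(
                f"lowercase RLE prefix {sym!r} at offset {i}: input already compressed?"
            )
        j = i
        while j < n and code[j] == sym:
            j += 1
        run = j - i
        while run > 0:
            block = min(run, 10)
            if block == 1:
                out.append(sym)
            else:
                out.append(prefixes[block] + sym)
            run -= block
        i = j
    return "".join(out)


def rle_decompress(code: str, table: dict[str, int] | None = None) -> str:
    """Exact inverse of :func:`rle_compress`."""
    lengths = table or RLE_LENGTHS
    out: list[str] = []
    i, n = 0, len(code)
    while i < n:
        c = code[i]
        if c in lengths:
            if i + 1 >= n:
                raise FormatError(f"dangling RLE prefix {c!r} at end of code")
            nxt = code[i + 1]
            if nxt in lengths:
                raise FormatError(f"RLE prefix {c!r} followed by prefix {nxt!r}")
            out.append(nxt * lengths[c])
            i += 2
        else:
            out.append(c)
            i += 1
    return "".join(out)


def slice_code(code: str, stride: int, phase: int = 0) -> str:
    """Keep symbols at indices congruent to *phase* modulo *stride*."""
    if stride < 1:
        raise InputError("stride must be >= 1")
    if not 0 <= phase < stride:
        raise InputError(f"phase must be in [0, {stride}), got {phase}")
    if stride == 1:
        return code
    return code[phase::stride]


def encode_sequence(
    seq: str, profile: EncodingProfile | None = None, phase: int = 0
) -> dict[str, WaveIdentity]:
    """Encode one sequence under *profile*, returning one identity per channel.

    Stage order per channel: gap extraction -> binning -> slicing (stride >
    1) -> RLE.  *phase* selects the slicing phase; a database is always
    built at phase 0 while queries against a sliced database try all phases.
    Deterministic: identical inputs give identical identities.
    """
    profile = profile or EncodingProfile()
    identities: dict[str, WaveIdentity] = {}
    for channel in profile.channels:
        series = extract_gap_series(seq, channel, profile)
        code = bin_series(series, profile.bin_table)
        if profile.slice_stride > 1:
            code = slice_code(code, profile.slice_stride, phase)
        if profile.use_rle:
            code = rle_compress(code)
        identities[channel] = WaveIdentity(
            channel=channel,
            code=code,
            source_length=len(seq),
            profile_id=profile.profile_id,
        )
    return identities


def pack_symbols(code: str) -> bytes:
    """Pack a code string at 5 bits per symbol (big-endian bit order).

    The final byte is zero-padded; the packed size is exactly
    ``ceil(5 * len(code) / 8)`` bytes.
    """
    if not code:
        return b""
    try:
        idx = np.array([_PACK_INDEX[c] for c in code], dtype=np.uint8)
    except KeyError as exc:
        raise FormatError(f"symbol {exc.args[0]!r} outside the packing alphabet") from None
    bits = np.unpackbits(idx[:, None], axis=1)[:, 3:].ravel()
    return np.packbits(bits).tobytes()


def unpack_symbols(data: bytes, n_symbols: int) -> str:
    """Exact inverse of :func:`pack_symbols` given the symbol count."""
    if n_symbols == 0:
        return ""
    expected = math.ceil(5 * n_symbols / 8)
    if len(data) != expected:
        raise FormatError(
            f"packed block of {len(data)} bytes cannot hold {n_symbols} symbols "
            f"(expected {expected})"
        )
    bits = np.unpackbits(np.frombuffer(data, dtype=np.uint8))[: 5 * n_symbols]
    groups = bits.reshape(n_symbols, 5)
    padded = np.concatenate(
        [np.zeros((n_symbols, 3), dtype=np.uint8), groups], axis=1
    )
    idx = np.packbits(padded, axis=1).ravel()
    if (idx >= len(PACK_ALPHABET)).any():
        raise FormatError("packed block decodes to a symbol outside the alphabet")
    alphabet = np.frombuffer(PACK_ALPHABET.encode("ascii"), dtype=np.uint8)
    return alphabet[idx].tobytes().decode("ascii")


def estimate_span(identity_slice: str, table: BinTable | None = None) -> float:
    """Approximate nucleotide span of a raw identity substring.

    Sums, per symbol, the midpoint of its bin range plus one (the channel
    base itself).  An estimate only: the true span is lost to binning.
    """
    table = table or BinTable()
    total = 0.0
    for c in identity_slice:
        if c in RLE_LENGTHS:
            raise InputError("estimate_span expects a raw (decompressed) code")
        total += table.midpoint(c) + 1
    return total
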