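import numpy as np
import pytest

from metawave.seq_io import CompressedDatabase, DbRecord
from metawave.wave_codec import EncodingProfile, WaveIdentity, encode_sequence


@pytest.fixture
def default_profile():
    return EncodingProfile()


@pytest.fixture
def make_db(default_profile):
    """Build a single-channel database directly from raw identity codes."""

    def _make(codes: dict[str, str], profile: EncodingProfile | None = None):
        profile = profile or default_profile
        records = [
            DbRecord(ref_id, 10 * len(code), {
                profile.channels[0]: WaveIdentity(
                    channel=profile.channels[0], code=code,
                    source_length=10 * len(code),
                    profile_id=profile.profile_id,
                )
            })
            for ref_id, code in codes.items()
        ]
        return CompressedDatabase(profile, records)

    return _make


@pytest.fixture
def make_seq_db():
    """Build a database by encoding nucleotide sequences."""

    def _make(seqs: dict[str, str], profile: EncodingProfile | None = None):
        profile = profile or EncodingProfile()
        records = [
            DbRecord(ref_id, len(seq), encode_sequence(seq, profile))
            for ref_id, seq in seqs.items()
        ]
        return CompressedDatabase(profile, records)

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(20241)
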