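"""Bloom-filter encodings of field values and the Dice similarity.

Fuzzy string fields are compared by splitting the normalised value into
n-grams (bigrams by default), hashing every n-gram into a fixed-length
bitfield and taking the Dice coefficient of the two parties' bitfields:

    S = 2 * Hw(Bl(x) & Bl(y)) / (Hw(Bl(x)) + Hw(Bl(y)))

where Hw is the Hamming weight (popcount).  A single-character change alters
at most 2 n-grams, hence at most 2k set bits, so small typos move the
similarity only slightly — this is what makes the linkage fault tolerant.

The Bloom filter here is purely a similarity data structure, not a privacy
mechanism (privacy comes from the secret-sharing layer); the hash salt is
public configuration and only ensures both parties map n-grams to identical
bit positions.  Each of the k indices is derived by double hashing,
``(h1 + j*h2) mod m``, from the two 64-bit halves of a keyed blake2b digest
of the n-gram.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Optional

import numpy as np

from .config import ABSENT, FieldSpec, LinkageConfig, PatientRecord

logger = logging.getLogger(__name__)

#: Sentinel character framing padded n-grams (spec flag ``padded``; off by default).
_PAD_CHAR = "#"


def ngrams(s: str, n: int) -> list[str]:
    """Contiguous substrings of length ``n`` in order, duplicates retained.

    A value shorter than ``n`` yields the single-element list ``[s]``.
    """
    if len(s) < n:
        return [s]
    return [s[i:i + n] for i in range(len(s) - n + 1)]


def _gram_indices(gram: str, m: int, k: int, salt: str) -> np.ndarray:
    """Double-hashed bit indices of one n-gram: (h1 + j*h2) mod m, j=0..k-1."""
    digest = hashlib.blake2b(gram.encode("utf-8"), digest_size=16,
                             key=salt.encode("utf-8")[:64]).digest()
    h1 = int.from_bytes(digest[:8], "little")
    h2 = int.from_bytes(digest[8:], "little")
    return (h1 + h2 * np.arange(k, dtype=np.uint64)) % np.uint64(m)


@dataclass
class BloomFilter:
    """Fixed-length bitset, packed little-endian (bit i = byte i//8, bit i%8)."""

    m: int
    k: int
    packed: np.ndarray  # uint8, length ceil(m/8)

    def popcount(self) -> int:
        return int(np.bitwise_count(self.packed).sum())

    def bits(self) -> np.ndarray:
        """Unpacked 0/1 array of length m."""
        return np.unpackbits(self.packed, bitorder="little")[: self.m]

    def __and__(self, other: "BloomFilter") -> "BloomFilter":
        if self.m != other.m:
            raise ValueError(f"filter length mismatch: {self.m} vs {other.m}")
        return BloomFilter(self.m, self.k, self.packed & other.packed)

    def to_hex(self) -> str:
        return self.packed.tobytes().hex()

    @classmethod
    def from_hex(cls, m: int, k: int, hexstr: str) -> "BloomFilter":
        packed = np.frombuffer(bytes.fromhex(hexstr), dtype=np.uint8).copy()
        if packed.size != (m + 7) // 8:
            raise ValueError("hex length does not match filter length")
        return cls(m, k, packed)


def bloom_encode(s: str, spec: FieldSpec, salt: str) -> BloomFilter:
    """Encode a normalised (non-ABSENT) value into a Bloom filter.

    Deterministic in (value, m, k, n, salt): two parties encoding the same
    normalised value under the same configuration produce bit-identical
    filters.
    """
    if s is ABSENT:
        raise ValueError("cannot Bloom-encode an ABSENT value")
    m, k, n = spec.bloom_len, spec.num_hashes, spec.ngram_len
    text = f"{_PAD_CHAR}{s}{_PAD_CHAR}" if spec.padded else s
    packed = np.zeros((m + 7) // 8, dtype=np.uint8)
    for gram in ngrams(text, n):
        idx = _gram_indices(gram, m, k, salt)
        np.bitwise_or.at(packed, (idx // 8).astype(np.intp),
                         np.left_shift(np.uint8(1), (idx % 8).astype(np.uint8)))
    return BloomFilter(m, k, packed)


def hamming_weight(bits: BloomFilter | np.ndarray) -> int:
    """Number of set bits of a filter or packed/unpacked bit array."""
    if isinstance(bits, BloomFilter):
        return bits.popcount()
    arr = np.asarray(bits)
    if arr.dtype == np.bool_:
        return int(arr.sum())
    return int(np.bitwise_count(arr).sum())


def dice(x: BloomFilter, y: BloomFilter) -> float:
    """Dice coefficient of two same-length filters, in [0, 1].

    The degenerate both-empty case is defined as 0 with a warning; it cannot
    occur for filters of present, non-empty normalised values.
    """
    if x.m != y.m:
        raise ValueError(f"filter length mismatch: {x.m} vs {y.m}")
    hx, hy = x.popcount(), y.popcount()
    if hx + hy == 0:
        logger.warning("dice of two empty filters; defined as 0")
        return 0.0
    inter = int(np.bitwise_count(x.packed & y.packed).sum())
    return 2.0 * inter / (hx + hy)


def token_hash(token: str, salt: str, bits: int = 32) -> int:
    """Fixed-width salted hash of a binary-comparator token.

    Used by the secure circuit to compare variable-length tokens as
    fixed-width bit strings; collision probability ~2^-bits per pair,
    negligible for the configured widths.
    """
    digest = hashlib.blake2b(token.encode("utf-8"), digest_size=8,
                             key=salt.encode("utf-8")[:64]).digest()
    return int.from_bytes(digest, "little") & ((1 << bits) - 1)


@dataclass
class EncodedField:
    """One field of an encoded record.

    ``present`` is False iff the value was ABSENT, in which case no payload
    is stored.  Dice fields carry a Bloom filter with its precomputed
    Hamming weight; binary fields carry the normalised token.
    """

    present: bool
    filter: Optional[BloomFilter] = None
    hw: int = 0
    token: Optional[str] = None


@dataclass
class EncodedRecord:
    fields: dict[str, EncodedField] = dc_field(default_factory=dict)


def encode_record(record: PatientRecord, config: LinkageConfig) -> EncodedRecord:
    """Precompute all per-field encodings of one record."""
    enc = EncodedRecord()
    for spec in config.fields:
        value = record.values[spec.name]
        if value is ABSENT:
            enc.fields[spec.name] = EncodedField(present=False)
        elif spec.comparator == "dice":
            bf = bloom_encode(value, spec, config.bloom_salt)
            enc.fields[spec.name] = EncodedField(present=True, filter=bf, hw=bf.popcount())
        else:
            enc.fields[spec.name] = EncodedField(present=True, token=value)
    return enc


def encode_records(records: list[PatientRecord], config: LinkageConfig) -> list[EncodedRecord]:
    return [encode_record(r, config) for r in records]


def dump_encodings(encoded: list[EncodedRecord], path: str | Path,
                   config: LinkageConfig) -> None:
    """Debug dump: one JSON object per line with hex filters and tokens."""
    with open(path, "w", encoding="utf-8") as fh:
        for rec in encoded:
            obj: dict[str, object] = {}
            for name, ef in rec.fields.items():
                if not ef.present:
                    obj[name] = None
                elif ef.filter is not None:
                    obj[name] = {"hex": ef.filter.to_hex(), "hw": ef.hw}
                else:
                    obj[name] = {"token": ef.token}
            fh.write(json.dumps(obj) + "\n")
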