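"""Plaintext EpiLink engine: similarities, classification, intersection counts.

A record pair's similarity is the normalised weighted sum of its per-field
similarities,

    score = sum_i w_i * s_i / sum_i w_i        (i over fields defined on both sides)

with two configurable thresholds: below the lower one the pair is a
NON_MATCH, at or above the upper one a MATCH, in between a TENTATIVE_MATCH
(ties resolve upward).  Exchange groups (e.g. first/sur/birth name) are
scored under every permutation of one side's group values against the fixed
slots of the other side, keeping the permutation that maximises the total
record score; slot weights stay with the slots.

Two arithmetic modes are provided:

* exact — real-valued scores, used for ordinary plaintext linkage;
* fixed-point — the integer arithmetic of the secure circuit (per-field
  similarities floored to p fractional bits, integerised weights, permutation
  tournament and classification via cross-multiplication).  This mode is the
  bit-exact oracle for the MPC path.

The module exposes both a per-record reference implementation and a
vectorised bulk engine (numpy, BLAS matmul popcounts) that the tests hold to
identical results.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from itertools import permutations, product
from typing import Optional, Sequence

import numpy as np

from .config import LinkageConfig, FieldSpec
from .encoding import EncodedField, EncodedRecord, dice, token_hash

logger = logging.getLogger(__name__)


class MatchClass(Enum):
    NON_MATCH = "non_match"
    TENTATIVE_MATCH = "tentative_match"
    MATCH = "match"


@dataclass
class SimilarityScore:
    """Record similarity in [0,1]; ``fixedpoint`` is floor(value * 2^p) as
    computed by the integer engine when requested."""

    value: float
    fixedpoint: Optional[int] = None


@dataclass
class BestMatch:
    index: int
    score: float
    match_class: MatchClass


@dataclass
class IntersectionResult:
    match_count: int
    tentative_count: int
    n_left: int
    n_right: int

    def to_dict(self) -> dict:
        return {
            "match_count": self.match_count,
            "tentative_count": self.tentative_count,
            "n_left": self.n_left,
            "n_right": self.n_right,
        }


# -- fixed-point parameters ---------------------------------------------------


@dataclass(frozen=True)
class FixedPointParams:
    """Derived integer-circuit parameters shared by the plaintext fixed-point
    engine and the secure circuit (identical derivation on both parties)."""

    p: int                       # fractional bits
    weights: dict[str, int]      # integerised weights w~ = round(W * w)
    t_tent_num: int
    t_tent_den: int
    t_match_num: int
    t_match_den: int
    tourn_bound_bits: int        # cross products N_a*M_b < 2^bits
    cls_bound_bits: int          # threshold products < 2^bits
    mass_bound_bits: int         # M < 2^bits

    @classmethod
    def from_config(cls, config: LinkageConfig) -> "FixedPointParams":
        p = config.fixedpoint_bits
        weights = {f.name: config.scaled_weight(f) for f in config.fields}
        wsum = sum(weights.values())
        t_t, t_m = config.threshold_fractions()
        bits_m = wsum.bit_length()
        bits_n = p + bits_m
        bits_tden = max(t_t.denominator, t_m.denominator).bit_length()
        bits_tnum = max(t_t.numerator, t_m.numerator).bit_length()
        return cls(
            p=p,
            weights=weights,
            t_tent_num=t_t.numerator,
            t_tent_den=t_t.denominator,
            t_match_num=t_m.numerator,
            t_match_den=t_m.denominator,
            tourn_bound_bits=bits_n + bits_m,
            cls_bound_bits=max(bits_n + bits_tden, bits_tnum + p + bits_m),
            mass_bound_bits=bits_m,
        )

    def quotient_bits(self) -> int:
        """Width of a per-field fixed-point similarity: s_fp <= 2^p."""
        return self.p + 1


# -- per-record reference path ------------------------------------------------


def field_similarity(a: EncodedField, b: EncodedField, spec: FieldSpec) -> Optional[float]:
    """Similarity of one field pair, or None (UNDEFINED) if either is ABSENT."""
    if not (a.present and b.present):
        return None
    if spec.comparator == "binary":
        return 1.0 if a.token == b.token else 0.0
    return dice(a.filter, b.filter)


def _field_sfp(a: EncodedField, b: EncodedField, spec: FieldSpec, p: int) -> tuple[int, int]:
    """Fixed-point field similarity floor(2^p * s) and the both-present bit.

    Mirrors the secure circuit exactly, including the degenerate
    present-but-empty-filter case (denominator 0) where the restoring
    divider saturates to all-ones; that case cannot arise for non-empty
    normalised values.
    """
    if not (a.present and b.present):
        return 0, 0
    if spec.comparator == "binary":
        return (int(a.token == b.token) << p), 1
    inter = int(np.bitwise_count(a.filter.packed & b.filter.packed).sum())
    den = a.hw + b.hw
    if den == 0:
        return (1 << (p + 1)) - 1, 1
    return ((2 * inter) << p) // den, 1


def _group_assignments(config: LinkageConfig):
    """Deterministic enumeration of exchange-group permutation combinations.

    The order (itertools.permutations per group, cartesian product across
    groups) is part of the cross-party contract: the oblivious tournament in
    the secure circuit walks candidates in this exact order.
    """
    return list(product(*[list(permutations(range(len(g)))) for g in config.exchange_groups]))


def record_similarity(x: EncodedRecord, y: EncodedRecord,
                      config: LinkageConfig) -> SimilarityScore:
    """Normalised weighted record similarity with exchange-group maximisation."""
    fmap = config.field_map
    num = 0.0
    den = 0.0
    for spec in config.non_group_fields:
        s = field_similarity(x.fields[spec.name], y.fields[spec.name], spec)
        if s is not None:
            w = spec.weight_value
            num += w * s
            den += w
    best = None
    for assignment in _group_assignments(config):
        gnum, gden = num, den
        for group, perm in zip(config.exchange_groups, assignment):
            for slot, src in enumerate(perm):
                spec = fmap[group[slot]]
                s = field_similarity(x.fields[group[slot]], y.fields[group[src]], spec)
                if s is not None:
                    w = spec.weight_value
                    gnum += w * s
                    gden += w
        score = gnum / gden if gden > 0 else 0.0
        if best is None or score > best:
            best = score
    if best is None:  # no exchange groups
        best = num / den if den > 0 else 0.0
    if best == 0.0 and den == 0.0:
        logger.warning("record pair has no field defined on both sides; score 0")
    return SimilarityScore(value=best)


def record_similarity_fixed(x: EncodedRecord, y: EncodedRecord, config: LinkageConfig,
                            fpp: Optional[FixedPointParams] = None) -> tuple[int, int]:
    """Integer score numerator N = sum w~_i s_i^fp and weight mass
    M = sum w~_i present_i of the tournament-winning candidate.

    Bit-exact mirror of the secure circuit (same candidate order, same
    challenger-wins-ties rule)."""
    fpp = fpp or FixedPointParams.from_config(config)
    fmap = config.field_map
    p = fpp.p
    n0 = 0
    m0 = 0
    for spec in config.non_group_fields:
        sfp, pp = _field_sfp(x.fields[spec.name], y.fields[spec.name], spec, p)
        w = fpp.weights[spec.name]
        n0 += w * sfp * pp
        m0 += w * pp
    candidates = []
    for assignment in _group_assignments(config):
        nc, mc = n0, m0
        for group, perm in zip(config.exchange_groups, assignment):
            for slot, src in enumerate(perm):
                spec = fmap[group[slot]]
                sfp, pp = _field_sfp(x.fields[group[slot]], y.fields[group[src]], spec, p)
                w = fpp.weights[group[slot]]
                nc += w * sfp * pp
                mc += w * pp
        candidates.append((nc, mc))
    best = candidates[0]
    for cand in candidates[1:]:
        if cand[0] * best[1] >= best[0] * cand[1]:  # challenger wins ties
            best = cand
    return best


def classify(score: float | SimilarityScore, config: LinkageConfig) -> MatchClass:
    """Two-threshold classification; scores equal to a threshold take the
    higher class."""
    value = score.value if isinstance(score, SimilarityScore) else score
    if value >= config.threshold_match:
        return MatchClass.MATCH
    if value >= config.threshold_tentative:
        return MatchClass.TENTATIVE_MATCH
    return MatchClass.NON_MATCH


def classify_fixed(n: int, m: int, fpp: FixedPointParams) -> MatchClass:
    """Division-free classification of an integer (N, M) score.

    match iff M >= 1 and N * t_den >= t_num * 2^p * M (ties upward); the
    M >= 1 gate mirrors the all-fields-absent rule of the exact engine."""
    if m < 1:
        return MatchClass.NON_MATCH
    if n * fpp.t_match_den >= (fpp.t_match_num << fpp.p) * m:
        return MatchClass.MATCH
    if n * fpp.t_tent_den >= (fpp.t_tent_num << fpp.p) * m:
        return MatchClass.TENTATIVE_MATCH
    return MatchClass.NON_MATCH


# -- vectorised bulk engine ---------------------------------------------------


def _pad_bytes(nbytes: int) -> int:
    return ((nbytes + 7) // 8) * 8


@dataclass
class EncodedDataset:
    """Columnar arrays of one party's encoded records (bulk/secure input)."""

    n: int
    config: LinkageConfig
    packed: dict[str, np.ndarray]        # dice fields: (n, padded bytes) uint8
    hw: dict[str, np.ndarray]            # dice fields: (n,) int64
    present: dict[str, np.ndarray]       # all fields: (n,) bool
    tokens: dict[str, list]              # binary fields: normalised tokens (None if absent)
    token_hashes: dict[str, np.ndarray]  # binary fields: (n,) uint64

    @classmethod
    def from_encoded(cls, records: Sequence[EncodedRecord],
                     config: LinkageConfig) -> "EncodedDataset":
        n = len(records)
        packed: dict[str, np.ndarray] = {}
        hw: dict[str, np.ndarray] = {}
        present: dict[str, np.ndarray] = {}
        tokens: dict[str, list] = {}
        hashes: dict[str, np.ndarray] = {}
        for spec in config.fields:
            name = spec.name
            present[name] = np.array([r.fields[name].present for r in records], dtype=bool)
            if spec.comparator == "dice":
                nbytes = _pad_bytes((spec.bloom_len + 7) // 8)
                arr = np.zeros((n, nbytes), dtype=np.uint8)
                hwv = np.zeros(n, dtype=np.int64)
                for i, r in enumerate(records):
                    ef = r.fields[name]
                    if ef.present:
                        arr[i, : ef.filter.packed.size] = ef.filter.packed
                        hwv[i] = ef.hw
                packed[name] = arr
                hw[name] = hwv
            else:
                toks = [r.fields[name].token if r.fields[name].present else None
                        for r in records]
                tokens[name] = toks
                hashes[name] = np.array(
                    [token_hash(t, config.token_salt, config.token_hash_bits)
                     if t is not None else 0 for t in toks], dtype=np.uint64)
        return cls(n=n, config=config, packed=packed, hw=hw, present=present,
                   tokens=tokens, token_hashes=hashes)


def as_dataset(data, config: LinkageConfig) -> EncodedDataset:
    if isinstance(data, EncodedDataset):
        return data
    return EncodedDataset.from_encoded(data, config)


class _BulkSims:
    """Per-chunk field-pair similarity matrices between A[rows] and all of B."""

    def __init__(self, dsA: EncodedDataset, dsB: EncodedDataset, config: LinkageConfig):
        self.dsA, self.dsB, self.config = dsA, dsB, config
        # unpacked B bit matrices for dice fields, float32 for BLAS popcount
        self._bitsB: dict[str, np.ndarray] = {}
        for spec in config.fields:
            if spec.comparator == "dice":
                bits = np.unpackbits(dsB.packed[spec.name], axis=1,
                                     bitorder="little")[:, : spec.bloom_len]
                self._bitsB[spec.name] = bits.astype(np.float32)
        # token codes for binary fields (shared code space per field)
        self._codesB: dict[str, np.ndarray] = {}
        self._codemap: dict[str, dict] = {}
        for spec in config.fields:
            if spec.comparator == "binary":
                mapping: dict = {}
                codes = np.empty(dsB.n, dtype=np.int64)
                for i, t in enumerate(dsB.tokens[spec.name]):
                    codes[i] = mapping.setdefault(t, len(mapping)) if t is not None else -2
                self._codesB[spec.name] = codes
                self._codemap[spec.name] = mapping

    def needed_pairs(self) -> list[tuple[str, str]]:
        """(field on A, field on B) similarity matrices the score needs."""
        pairs = [(f.name, f.name) for f in self.config.non_group_fields]
        for group in self.config.exchange_groups:
            pairs.extend((fa, fb) for fa in group for fb in group)
        return pairs

    def sim(self, rows: np.ndarray, fa: str, fb: str):
        """(S, PP, inter, den) for A[rows] x B on field pair (fa, fb).

        S float64 similarity, PP bool both-present, and for dice fields the
        integer intersection popcount and Hamming-weight sum used by the
        fixed-point path (inter/den are None for binary fields)."""
        spec = self.config.field_map[fa]
        ppa = self.dsA.present[fa][rows]
        pp = ppa[:, None] & self.dsB.present[fb][None, :]
        if spec.comparator == "dice":
            bitsA = np.unpackbits(self.dsA.packed[fa][rows], axis=1,
                                  bitorder="little")[:, : spec.bloom_len].astype(np.float32)
            inter = np.rint(bitsA @ self._bitsB[fb].T).astype(np.int64)
            den = self.dsA.hw[fa][rows][:, None] + self.dsB.hw[fb][None, :]
            with np.errstate(divide="ignore", invalid="ignore"):
                s = np.where(den > 0, 2.0 * inter / den, 0.0)
            return s, pp, inter, den
        mapping = self._codemap[fb]
        codesA = np.array([mapping.get(t, -1) if t is not None else -3
                           for t in (self.dsA.tokens[fa][i] for i in rows)], dtype=np.int64)
        eq = codesA[:, None] == self._codesB[fb][None, :]
        return eq.astype(np.float64), pp, None, None


def _chunk_ranges(n: int, chunk: int):
    for start in range(0, n, chunk):
        yield np.arange(start, min(start + chunk, n))


def link_pair(A, B, config: LinkageConfig, chunk: int = 256) -> list[BestMatch]:
    """Best B-match (lowest index on ties) and its class for every A record."""
    dsA, dsB = as_dataset(A, config), as_dataset(B, config)
    if dsA.n == 0 or dsB.n == 0:
        raise ValueError("link_pair requires nonempty datasets")
    sims = _BulkSims(dsA, dsB, config)
    fmap = config.field_map
    assignments = _group_assignments(config)
    results: list[BestMatch] = []
    for rows in _chunk_ranges(dsA.n, chunk):
        cache = {pair: sims.sim(rows, *pair)[:2] for pair in sims.needed_pairs()}
        num0 = np.zeros((rows.size, dsB.n))
        den0 = np.zeros_like(num0)
        for spec in config.non_group_fields:
            s, pp = cache[(spec.name, spec.name)]
            w = spec.weight_value
            num0 += w * (s * pp)
            den0 += w * pp
        best = None
        for assignment in assignments:
            gnum, gden = num0.copy(), den0.copy()
            for group, perm in zip(config.exchange_groups, assignment):
                for slot, src in enumerate(perm):
                    s, pp = cache[(group[slot], group[src])]
                    w = fmap[group[slot]].weight_value
                    gnum += w * (s * pp)
                    gden += w * pp
            with np.errstate(divide="ignore", invalid="ignore"):
                score = np.where(gden > 0, gnum / gden, 0.0)
            best = score if best is None else np.maximum(best, score)
        if best is None:
            with np.errstate(divide="ignore", invalid="ignore"):
                best = np.where(den0 > 0, num0 / den0, 0.0)
        idx = np.argmax(best, axis=1)
        top = best[np.arange(rows.size), idx]
        for j, (bi, sc) in enumerate(zip(idx, top)):
            results.append(BestMatch(index=int(bi), score=float(sc),
                                     match_class=classify(float(sc), config)))
    return results


def pairwise_classes_fixed(A, B, config: LinkageConfig,
                           fpp: Optional[FixedPointParams] = None,
                           chunk: int = 256) -> tuple[np.ndarray, np.ndarray]:
    """Per-pair fixed-point classification bits (is_match, is_tentative_or_match).

    This is the plaintext oracle for the secure circuit: identical integer
    arithmetic, candidate order, tie rules and the M >= 1 gate."""
    dsA, dsB = as_dataset(A, config), as_dataset(B, config)
    fpp = fpp or FixedPointParams.from_config(config)
    sims = _BulkSims(dsA, dsB, config)
    p = fpp.p
    sat = (1 << (p + 1)) - 1
    assignments = _group_assignments(config)
    is_match = np.zeros((dsA.n, dsB.n), dtype=bool)
    is_tom = np.zeros_like(is_match)
    for rows in _chunk_ranges(dsA.n, chunk):
        cache = {}
        for pair in sims.needed_pairs():
            s, pp, inter, den = sims.sim(rows, *pair)
            spec = sims.config.field_map[pair[0]]
            if spec.comparator == "dice":
                with np.errstate(divide="ignore", invalid="ignore"):
                    sfp = np.where(den > 0, ((2 * inter) << p) // np.maximum(den, 1), sat)
            else:
                sfp = (s.astype(np.int64)) << p
            cache[pair] = (sfp * pp, pp.astype(np.int64))
        n0 = np.zeros((rows.size, dsB.n), dtype=np.int64)
        m0 = np.zeros_like(n0)
        for spec in config.non_group_fields:
            sfp, pp = cache[(spec.name, spec.name)]
            w = fpp.weights[spec.name]
            n0 += w * sfp
            m0 += w * pp
        bn, bm = None, None
        for assignment in assignments:
            nc, mc = n0.copy(), m0.copy()
            for group, perm in zip(config.exchange_groups, assignment):
                for slot, src in enumerate(perm):
                    sfp, pp = cache[(group[slot], group[src])]
                    w = fpp.weights[group[slot]]
                    nc += w * sfp
                    mc += w * pp
            if bn is None:
                bn, bm = nc, mc
            else:
                win = nc * bm >= bn * mc
                bn = np.where(win, nc, bn)
                bm = np.where(win, mc, bm)
        nz = bm >= 1
        is_match[rows] = nz & (bn * fpp.t_match_den >= (fpp.t_match_num << p) * bm)
        is_tom[rows] = nz & (bn * fpp.t_tent_den >= (fpp.t_tent_num << p) * bm)
    return is_match, is_tom


def intersection_cardinality_plain(A, B, config: LinkageConfig, mode: str = "exact",
                                   one_to_one: bool = False,
                                   chunk: int = 256) -> IntersectionResult:
    """Counts of A records with a MATCH (resp. best-effort TENTATIVE) in B.

    ``mode='fixed'`` uses the secure circuit's integer arithmetic and the
    any-pair semantics of the cardinality circuit (a record counts as a match
    if any B record classifies MATCH against it; since classification is
    monotone in the score, this coincides with classifying the best match).
    """
    dsA, dsB = as_dataset(A, config), as_dataset(B, config)
    if dsA.n == 0 or dsB.n == 0:
        raise ValueError("intersection requires nonempty datasets")
    if mode == "fixed":
        is_match, is_tom = pairwise_classes_fixed(dsA, dsB, config, chunk=chunk)
        row_match = is_match.any(axis=1)
        row_tent = is_tom.any(axis=1) & ~row_match
        return IntersectionResult(int(row_match.sum()), int(row_tent.sum()),
                                  dsA.n, dsB.n)
    best = link_pair(dsA, dsB, config, chunk=chunk)
    if one_to_one:
        order = sorted(range(dsA.n), key=lambda i: -best[i].score)
        used: set[int] = set()
        match_count = tentative_count = 0
        for i in order:
            if best[i].match_class is MatchClass.NON_MATCH or best[i].index in used:
                continue
            used.add(best[i].index)
            if best[i].match_class is MatchClass.MATCH:
                match_count += 1
            else:
                tentative_count += 1
        return IntersectionResult(match_count, tentative_count, dsA.n, dsB.n)
    match_count = sum(1 for b in best if b.match_class is MatchClass.MATCH)
    tentative_count = sum(1 for b in best if b.match_class is MatchClass.TENTATIVE_MATCH)
    return IntersectionResult(match_count, tentative_count, dsA.n, dsB.n)


def multiway_overlap(A, B, C, config: LinkageConfig, chunk: int = 256) -> int:
    """Records of A with a MATCH in both B and C, via two pairwise linkages.

    The pairwise composition is this package's construction: the underlying
    similarity is not transitive, so a direct three-way similarity is out of
    scope."""
    bm_b = link_pair(A, B, config, chunk=chunk)
    bm_c = link_pair(A, C, config, chunk=chunk)
    return sum(1 for x, y in zip(bm_b, bm_c)
               if x.match_class is MatchClass.MATCH and y.match_class is MatchClass.MATCH)
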