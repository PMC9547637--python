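"""The oblivious record-linkage circuit: reveal only the intersection counts.

Party 0 holds dataset A, party 1 dataset B.  After an in-clear configuration
digest handshake, each party secret-shares its encoded records (Bloom-filter
bits and presence bits as Boolean shares, Hamming weights as ring shares,
binary-field tokens as fixed-width salted hashes).  The circuit then mirrors
the plaintext fixed-point engine gate by gate:

* per field pair: shared Hw(x & y) via Beaver AND and bit-to-ring conversion,
  then the fixed-point Dice quotient floor(2^p * 2*Hw(x&y) / (Hw(x)+Hw(y)))
  from a restoring long-division circuit on Boolean shares; binary fields use
  an equality AND-tree scaled by 2^p; all gated by the both-present bit;
* record score: integerised weights accumulate shared (N, M) sums; each
  exchange-group permutation is a candidate, and an oblivious tournament
  keeps the larger N/M ratio via the division-free comparison
  N_a * M_b >= N_b * M_a;
* classification: N * t_den >= t_num * 2^p * M for both thresholds (and
  M >= 1, the all-fields-absent guard);
* cardinality: per-A-record OR over all B pairs, bit-to-ring, summed.

Only the two aggregate counts are ever reconstructed; the per-pair match
bits never leave share form (audited via the runtime's reveal counter).

A setup-phase tally pass runs the same circuit on shape-identical zero
inputs against a counting dealer stub; the dealer then materialises exactly
the tallied correlated randomness and the online pass must exhaust it.
"""

from __future__ import annotations

import time
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .config import LinkageConfig, config_digest
from .linkage import (EncodedDataset, FixedPointParams, IntersectionResult,
                      _group_assignments, as_dataset)
from .mpc import (CountingBundle, Dealer, InProcChannel, MPCError, PartyRuntime,
                  ProtocolAbort, _bitmask, _packed_dtype, run_pair)


@dataclass
class SecureRunStats:
    """Setup/online accounting of one secure run (per-party symmetric)."""

    setup_counts: dict[str, int]
    setup_seconds: float
    online_seconds: float
    online_bytes: int
    online_messages: int
    reveal_count: int

    def to_dict(self) -> dict:
        return {
            "setup_counts": self.setup_counts,
            "setup_seconds": self.setup_seconds,
            "online_seconds": self.online_seconds,
            "online_bytes": self.online_bytes,
            "online_messages": self.online_messages,
            "reveal_count": self.reveal_count,
        }


def _const_share(rt: PartyRuntime, value: int, shape) -> np.ndarray:
    """Ring shares of a public constant (party 0 holds it, party 1 zero)."""
    return np.full(shape, value if rt.party == 0 else 0, dtype=np.uint64)


def _eq_fold(rt: PartyRuntime, z: np.ndarray, width: int) -> np.ndarray:
    """Shares of [z == 0] for a bit-packed shared word via an AND tree of the
    complemented bits (log2(width) Beaver rounds)."""
    cur = rt.not_bits(z, width)
    w = width
    while w > 1:
        half = (w + 1) // 2
        lo = cur & _bitmask(half, cur.dtype)
        hi = cur >> cur.dtype.type(half)
        if rt.party == 0 and w - half < half:
            # pad the short top half with public ones (AND identity)
            hi = hi ^ (_bitmask(half, cur.dtype) ^ _bitmask(w - half, cur.dtype))
        cur = rt.and_bits(lo, hi)
        w = half
    return (cur & cur.dtype.type(1)).astype(np.uint8)


def _or_reduce_axis1(rt: PartyRuntime, mat: np.ndarray) -> np.ndarray:
    """OR of single-bit shares along axis 1 (NOT-AND tree; zero padding is a
    public OR identity)."""
    cur = mat
    while cur.shape[1] > 1:
        k = cur.shape[1]
        if k % 2:
            cur = np.concatenate([cur, np.zeros((cur.shape[0], 1), dtype=cur.dtype)],
                                 axis=1)
        half = cur.shape[1] // 2
        cur = rt.or_bits(cur[:, :half], cur[:, half:])
    return cur[:, 0]


def secure_dice_similarity(rt: PartyRuntime, filt_a: np.ndarray, filt_b: np.ndarray,
                           hw_a: np.ndarray, hw_b: np.ndarray, m: int,
                           p: int) -> np.ndarray:
    """Ring shares of floor(2^p * Dice) for aligned rows of shared filters.

    Shared Hw(a & b) comes from a Beaver AND plus per-bit ring conversion;
    the quotient floor(2^(p+1) * Hw(a&b) / (Hw(a) + Hw(b))) is produced by a
    restoring division circuit on Boolean shares.  A zero denominator (both
    values absent or empty) saturates; callers gate by the presence bit.
    """
    n_rows = filt_a.shape[0]
    inter = rt.and_bits(filt_a, filt_b)
    bits = np.unpackbits(np.ascontiguousarray(inter).view(np.uint8),
                         axis=1, bitorder="little")[:, :m]
    # narrow-ring conversion: the bit sum is bounded by m, so Z_2^16 suffices
    hw_inter = rt.b2a16(bits.reshape(-1)).reshape(n_rows, m).sum(axis=1,
                                                                 dtype=np.uint16)
    den = hw_a + hw_b
    hw_bits = m.bit_length()
    den_bits = (2 * m).bit_length()
    q_bits = p + 1
    num_bits = hw_bits + p + 1
    work_dtype = _packed_dtype(max(num_bits, den_bits + 1))
    num_packed = rt.a2b(hw_inter, hw_bits).astype(work_dtype) << work_dtype(p + 1)
    den_packed = rt.a2b(den, den_bits).astype(work_dtype)
    q = rt.divide_packed(num_packed, num_bits, den_packed, q_bits, den_bits + 1)
    planes = np.stack([((q >> work_dtype(j)) & work_dtype(1)).astype(np.uint8)
                       for j in range(q_bits)])
    q_ring = rt.b2a(planes.reshape(-1)).reshape(q_bits, n_rows)
    sfp = np.zeros(n_rows, dtype=np.uint64)
    for j in range(q_bits):
        sfp = sfp + q_ring[j] * np.uint64(1 << j)
    return sfp


def _sim_pairs(config: LinkageConfig) -> list[tuple[str, str]]:
    """Field-pair similarity circuits in deterministic order (matches the
    plaintext bulk engine)."""
    pairs = [(f.name, f.name) for f in config.non_group_fields]
    for group in config.exchange_groups:
        pairs.extend((fa, fb) for fa in group for fb in group)
    return pairs


def _epilink_program(channel: InProcChannel, party: int, ds_own: EncodedDataset,
                     n_a: int, n_b: int, config: LinkageConfig,
                     fpp: FixedPointParams, bundle, rng: np.random.Generator,
                     digest: str):
    """The per-party online program; returns (match_count, tentative_count)."""
    rt = PartyRuntime(party, channel, bundle, rng)
    fmap = config.field_map
    p = fpp.p

    # -- configuration handshake (in clear, before any sharing) -----------
    mine = np.frombuffer(digest.encode("ascii"), dtype=np.uint8)
    theirs = rt.exchange(mine)
    if theirs.shape != mine.shape or not np.array_equal(mine, theirs):
        raise ProtocolAbort("linkage configuration digest mismatch")

    # -- input sharing -----------------------------------------------------
    filt: dict[tuple[int, str], np.ndarray] = {}
    hw: dict[tuple[int, str], np.ndarray] = {}
    pres: dict[tuple[int, str], np.ndarray] = {}
    tok: dict[tuple[int, str], np.ndarray] = {}
    tok_dtype = _packed_dtype(config.token_hash_bits)
    for owner, n_rows in ((0, n_a), (1, n_b)):
        own = ds_own if party == owner else None
        for spec in config.fields:
            name = spec.name
            if spec.comparator == "dice":
                words = own.packed[name].shape[1] // 8 if own is not None else \
                    ((spec.bloom_len + 7) // 8 + 7) // 8
                value = own.packed[name].view(np.uint64) if own is not None else None
                filt[(owner, name)] = rt.input_bits(owner, value, (n_rows, words),
                                                    np.uint64, 64)
                hw_val = own.hw[name].astype(np.uint64) if own is not None else None
                hw[(owner, name)] = rt.input_ring(owner, hw_val, (n_rows,))
            else:
                tv = own.token_hashes[name].astype(tok_dtype) if own is not None else None
                tok[(owner, name)] = rt.input_bits(owner, tv, (n_rows,), tok_dtype,
                                                   config.token_hash_bits)
            pv = own.present[name].astype(np.uint8) if own is not None else None
            pres[(owner, name)] = rt.input_bits(owner, pv, (n_rows,), np.uint8, 1)

    # -- pair expansion (local share indexing) -----------------------------
    ia = np.repeat(np.arange(n_a), n_b)
    ib = np.tile(np.arange(n_b), n_a)
    n_pairs = n_a * n_b

    # -- field-pair similarities -------------------------------------------
    s_gated: dict[tuple[str, str], np.ndarray] = {}
    ppa: dict[tuple[str, str], np.ndarray] = {}
    for fa, fb in _sim_pairs(config):
        spec = fmap[fa]
        pp = rt.and_bits(pres[(0, fa)][ia], pres[(1, fb)][ib])
        pp_ring = rt.b2a(pp)
        if spec.comparator == "binary":
            z = tok[(0, fa)][ia] ^ tok[(1, fb)][ib]
            eq = _eq_fold(rt, z, config.token_hash_bits)
            em = rt.and_bits(eq, pp)  # equal AND both present
            s_gated[(fa, fb)] = rt.b2a(em) * np.uint64(1 << p)
        else:
            sfp = secure_dice_similarity(rt, filt[(0, fa)][ia], filt[(1, fb)][ib],
                                         hw[(0, fa)][ia], hw[(1, fb)][ib],
                                         spec.bloom_len, p)
            s_gated[(fa, fb)] = rt.mul(pp_ring, sfp)
        ppa[(fa, fb)] = pp_ring

    # -- record score: weighted sums + oblivious permutation tournament ----
    n0 = np.zeros(n_pairs, dtype=np.uint64)
    m0 = np.zeros(n_pairs, dtype=np.uint64)
    for spec in config.non_group_fields:
        w = fpp.weights[spec.name]
        n0 = n0 + s_gated[(spec.name, spec.name)] * np.uint64(w)
        m0 = m0 + ppa[(spec.name, spec.name)] * np.uint64(w)
    candidates = []
    for assignment in _group_assignments(config):
        nc, mc = n0.copy(), m0.copy()
        for group, perm in zip(config.exchange_groups, assignment):
            for slot, src in enumerate(perm):
                w = np.uint64(fpp.weights[group[slot]])
                nc = nc + s_gated[(group[slot], group[src])] * w
                mc = mc + ppa[(group[slot], group[src])] * w
        candidates.append((nc, mc))
    best_n, best_m = candidates[0]
    for nc, mc in candidates[1:]:
        lhs = rt.mul(nc, best_m)
        rhs = rt.mul(best_n, mc)
        win = rt.compare_ge(lhs, rhs, fpp.tourn_bound_bits)  # challenger wins ties
        win_ring = rt.b2a(win)
        best_n = rt.mux_ca(win_ring, nc, best_n)
        best_m = rt.mux_ca(win_ring, mc, best_m)

    # -- classification ----------------------------------------------------
    nonzero = rt.compare_ge(best_m, _const_share(rt, 1, n_pairs),
                            fpp.mass_bound_bits)
    is_match = rt.and_bits(
        rt.compare_ge(best_n * np.uint64(fpp.t_match_den),
                      best_m * np.uint64(fpp.t_match_num << p),
                      fpp.cls_bound_bits),
        nonzero)
    is_tom = rt.and_bits(
        rt.compare_ge(best_n * np.uint64(fpp.t_tent_den),
                      best_m * np.uint64(fpp.t_tent_num << p),
                      fpp.cls_bound_bits),
        nonzero)

    # -- cardinality: OR over B, convert, sum; reveal only the two counts --
    match_row = _or_reduce_axis1(rt, is_match.reshape(n_a, n_b))
    tom_row = _or_reduce_axis1(rt, is_tom.reshape(n_a, n_b))
    tent_row = rt.and_bits(tom_row, rt.not_bits(match_row))
    match_sum = rt.b2a(match_row).sum(dtype=np.uint64).reshape(1)
    tent_sum = rt.b2a(tent_row).sum(dtype=np.uint64).reshape(1)
    match_count = int(rt.reveal_ring(match_sum)[0])
    tentative_count = int(rt.reveal_ring(tent_sum)[0])
    bundle.assert_exhausted()
    return match_count, tentative_count, rt.reveal_count


def _dummy_dataset(n: int, config: LinkageConfig) -> EncodedDataset:
    """Shape-identical all-zero stand-in used by the input-independent tally
    pass (consumable counts depend only on sizes and configuration)."""
    packed, hw, present, tokens, hashes = {}, {}, {}, {}, {}
    for spec in config.fields:
        if spec.comparator == "dice":
            nbytes = (((spec.bloom_len + 7) // 8 + 7) // 8) * 8
            packed[spec.name] = np.zeros((n, nbytes), dtype=np.uint8)
            hw[spec.name] = np.zeros(n, dtype=np.int64)
        else:
            tokens[spec.name] = [None] * n
            hashes[spec.name] = np.zeros(n, dtype=np.uint64)
        present[spec.name] = np.zeros(n, dtype=bool)
    return EncodedDataset(n=n, config=config, packed=packed, hw=hw,
                          present=present, tokens=tokens, token_hashes=hashes)


def secure_intersection_cardinality(
    A, B, config: LinkageConfig, seed: int,
    config_b: Optional[LinkageConfig] = None,
    return_stats: bool = False,
):
    """Run the full two-party protocol in-process and return the revealed
    :class:`IntersectionResult` (optionally with setup/online statistics).

    ``config_b`` lets party 1 run under a different configuration, which must
    abort during the digest handshake; it exists for testing that abort path.
    """
    cfg_b = config_b or config
    ds_a = as_dataset(A, config)
    ds_b = as_dataset(B, cfg_b)
    if ds_a.n == 0 or ds_b.n == 0:
        raise ValueError("secure intersection requires nonempty datasets")
    fpp = FixedPointParams.from_config(config)
    fpp_b = FixedPointParams.from_config(cfg_b)
    dig_a, dig_b = config_digest(config), config_digest(cfg_b)
    ss = np.random.SeedSequence(seed)
    dealer_seed, rng0_seed, rng1_seed = ss.spawn(3)

    def program(bundles, rngs):
        def prog0(ch):
            return _epilink_program(ch, 0, bundles[0][2], ds_a.n, ds_b.n, config,
                                    fpp, bundles[0][0], rngs[0], dig_a)

        def prog1(ch):
            return _epilink_program(ch, 1, bundles[1][2], ds_a.n, ds_b.n, cfg_b,
                                    fpp_b, bundles[1][0], rngs[1], dig_b)

        return prog0, prog1

    # setup phase: tally pass on zero inputs, then dealer materialisation
    t0 = time.perf_counter()
    tally0, tally1 = CountingBundle(), CountingBundle()
    dummy_a, dummy_b = _dummy_dataset(ds_a.n, config), _dummy_dataset(ds_b.n, cfg_b)
    p0, p1 = program(((tally0, None, dummy_a), (tally1, None, dummy_b)),
                     (np.random.default_rng(rng0_seed), np.random.default_rng(rng1_seed)))
    run_pair(p0, p1)
    if tally0.counts != tally1.counts:
        raise MPCError("asymmetric consumable tallies")
    bundle0, bundle1 = Dealer(dealer_seed).generate(tally0.counts)
    setup_seconds = time.perf_counter() - t0

    # online phase
    t1 = time.perf_counter()
    p0, p1 = program(((bundle0, None, ds_a), (bundle1, None, ds_b)),
                     (np.random.default_rng(rng0_seed), np.random.default_rng(rng1_seed)))
    res0, res1, (ch0, ch1) = run_pair(p0, p1)
    online_seconds = time.perf_counter() - t1
    if res0[:2] != res1[:2]:
        raise MPCError(f"parties disagree on revealed counts: {res0} vs {res1}")
    if res0[2] != 2 or res1[2] != 2:
        raise MPCError("reconstruction audit failed: expected exactly two reveals")
    result = IntersectionResult(match_count=res0[0], tentative_count=res0[1],
                                n_left=ds_a.n, n_right=ds_b.n)
    if not return_stats:
        return result
    stats = SecureRunStats(
        setup_counts=dict(tally0.counts),
        setup_seconds=setup_seconds,
        online_seconds=online_seconds,
        online_bytes=ch0.bytes_sent + ch0.bytes_received,
        online_messages=ch0.messages + ch1.messages,
        reveal_count=res0[2],
    )
    return result, stats
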