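import numpy as np
import pytest
from scipy import stats

from seclink.mpc import (ConsumableExhausted, Dealer, MPCError, PartyBundle,
                         dealer_generate, reconstruct_bits, reconstruct_ring,
                         share_bits, share_ring)
from seclink.secure import _eq_fold

M64 = np.uint64(0xFFFFFFFFFFFFFFFF)


# -- sharing primitives (general n) ------------------------------------------


def test_share_bool_roundtrip_exhaustive_8bit():
    rng = np.random.default_rng(0)
    values = np.arange(256, dtype=np.uint8)
    for n in (2, 3, 5):
        shares = share_bits(values, n, rng)
        assert len(shares) == n
        assert np.array_equal(reconstruct_bits(shares), values)


def test_share_bool_fixed_example():
    # v=1 with shares (1, 0, 0) xors back to 1
    assert reconstruct_bits([np.uint8(1), np.uint8(0), np.uint8(0)]) == 1


def test_share_requires_two_parties_and_matching_widths():
    rng = np.random.default_rng(0)
    with pytest.raises(MPCError):
        share_bits(np.zeros(4, dtype=np.uint8), 1, rng)
    with pytest.raises(MPCError):
        reconstruct_bits([np.zeros(4, dtype=np.uint8), np.zeros(5, dtype=np.uint8)])


def test_share_bool_marginal_uniform_chisquare():
    # first share of a fixed secret should look uniform over repeated sharings
    rng = np.random.default_rng(123)
    secret = np.zeros(1, dtype=np.uint8)
    samples = np.array([share_bits(secret, 2, rng)[0][0] for _ in range(10_000)])
    counts = np.bincount(samples, minlength=256)
    assert stats.chisquare(counts).pvalue > 1e-3


def test_share_arith_example_and_roundtrip():
    # shares (200, 56, 5) on Z_256 reconstruct 261 mod 256 = 5
    shares = [np.array([200], dtype=np.uint64), np.array([56], dtype=np.uint64),
              np.array([5], dtype=np.uint64)]
    assert reconstruct_ring(shares, ring_bits=8)[0] == 5
    rng = np.random.default_rng(1)
    values = rng.integers(0, 2 ** 62, size=1000, dtype=np.uint64)
    for n in (2, 4):
        assert np.array_equal(reconstruct_ring(share_ring(values, n, rng)), values)
    zero = share_ring(np.zeros(10, dtype=np.uint64), 3, rng, ring_bits=16)
    assert np.all(reconstruct_ring(zero, 16) == 0)
    with pytest.raises(MPCError):
        share_ring(np.array([300], dtype=np.uint64), 2, rng, ring_bits=8)


# -- dealer -------------------------------------------------------------------


def test_dealer_triple_defining_relations():
    b0, b1 = dealer_generate({"bool_u8": 500, "bool_u64": 100, "arith": 300,
                              "b2a": 400}, seed=5)
    for key in ("bool_u8", "bool_u64"):
        a0, x0, c0 = b0.bool_pools[key]
        a1, x1, c1 = b1.bool_pools[key]
        assert np.array_equal(c0 ^ c1, (a0 ^ a1) & (x0 ^ x1))
    a0, x0, c0 = b0.arith_pool
    a1, x1, c1 = b1.arith_pool
    assert np.array_equal(c0 + c1, (a0 + a1) * (x0 + x1))
    r0, ra0 = b0.b2a_pool
    r1, ra1 = b1.b2a_pool
    assert np.array_equal(ra0 + ra1, (r0 ^ r1).astype(np.uint64))
    assert b0.phase == "setup"


def test_bundle_sizes_exhaustion_and_no_reuse():
    b0, _ = dealer_generate({"bool_u8": 10, "arith": 4, "b2a": 0}, seed=2)
    a, b, c = b0.take_bool(6, np.uint8)
    assert a.size == 6
    b0.take_bool(4, np.uint8)  # pool now empty; sequential consumption = no reuse
    with pytest.raises(ConsumableExhausted):
        b0.take_bool(1, np.uint8)
    with pytest.raises(ConsumableExhausted):
        b0.assert_exhausted()  # arith pool untouched
    b0.take_arith(4)
    b0.assert_exhausted()


# -- online gates vs plaintext oracles ---------------------------------------


def _shared_inputs(rt, x, y, dtype, width):
    xs = rt.input_bits(0, x if rt.party == 0 else None, x.shape, dtype, width)
    ys = rt.input_bits(1, y if rt.party == 1 else None, y.shape, dtype, width)
    return xs, ys


def test_xor_is_local_and_correct(two_party):
    x = np.array([0b1010], dtype=np.uint8)
    y = np.array([0b0110], dtype=np.uint8)

    def prog(rt):
        xs, ys = _shared_inputs(rt, x, y, np.uint8, 8)
        assert rt.channel.messages <= 2  # only the two input-mask messages
        before = rt.channel.messages
        z = xs ^ ys
        zz = xs ^ xs
        assert rt.channel.messages == before  # XOR needs no communication
        return z, zz

    (z0, zz0), (z1, zz1) = two_party(prog)
    assert (z0 ^ z1)[0] == 0b1100
    assert (zz0 ^ zz1)[0] == 0


def test_and_gate_exhaustive_and_absorbing(two_party):
    combos = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=np.uint8)
    x, y = combos[:, 0].copy(), combos[:, 1].copy()

    def prog(rt):
        xs, ys = _shared_inputs(rt, x, y, np.uint8, 1)
        z = rt.and_bits(xs, ys)
        zero = rt.and_bits(xs, np.zeros_like(xs))  # x & 0 (public zero share)
        return z, zero

    (z0, a0), (z1, a1) = two_party(prog)
    assert np.array_equal((z0 ^ z1) & 1, x & y)
    assert np.all(((a0 ^ a1) & 1) == 0)


def test_and_gate_words_randomized(two_party):
    rng = np.random.default_rng(8)
    x = rng.integers(0, 2 ** 64, size=200, dtype=np.uint64)
    y = rng.integers(0, 2 ** 64, size=200, dtype=np.uint64)

    def prog(rt):
        xs, ys = _shared_inputs(rt, x, y, np.uint64, 64)
        return rt.and_bits(xs, ys)

    z0, z1 = two_party(prog)
    assert np.array_equal(z0 ^ z1, x & y)


def test_mul_matches_plaintext_product(two_party):
    rng = np.random.default_rng(9)
    x = rng.integers(0, 2 ** 16, size=1000, dtype=np.uint64)
    y = rng.integers(0, 2 ** 16, size=1000, dtype=np.uint64)

    def prog(rt):
        xs = rt.input_ring(0, x if rt.party == 0 else None, x.shape)
        ys = rt.input_ring(1, y if rt.party == 1 else None, y.shape)
        one = np.full(x.shape, 1 if rt.party == 0 else 0, dtype=np.uint64)
        zero = np.zeros(x.shape, dtype=np.uint64)
        return rt.mul(xs, ys), rt.mul(xs, one), rt.mul(xs, zero)

    (p0, i0, z0), (p1, i1, z1) = two_party(prog)
    assert np.array_equal(p0 + p1, x * y)
    assert np.array_equal(i0 + i1, x)  # x * 1 = x
    assert np.all(z0 + z1 == 0)        # x * 0 = 0


def test_b2a_exhaustive_and_randomized(two_party):
    rng = np.random.default_rng(10)
    bits = np.concatenate([[0, 1], rng.integers(0, 2, size=1000)]).astype(np.uint8)

    def prog(rt):
        sh = rt.input_bits(0, bits if rt.party == 0 else None, bits.shape,
                           np.uint8, 1)
        return rt.b2a(sh)

    r0, r1 = two_party(prog)
    assert np.array_equal(r0 + r1, bits.astype(np.uint64))


def test_a2b_roundtrip_randomized(two_party):
    rng = np.random.default_rng(11)
    values = np.concatenate([[0, (1 << 20) - 1],
                             rng.integers(0, 1 << 20, size=1000)]).astype(np.uint64)

    def prog(rt):
        sh = rt.input_ring(0, values if rt.party == 0 else None, values.shape)
        return rt.a2b(sh, 20)

    r0, r1 = two_party(prog)
    assert np.array_equal((r0 ^ r1).astype(np.uint64), values)


def test_compare_ge_oracle_with_ties(two_party):
    rng = np.random.default_rng(12)
    u = rng.integers(0, 2 ** 40, size=500, dtype=np.uint64)
    v = rng.integers(0, 2 ** 40, size=500, dtype=np.uint64)
    u[:5] = v[:5]  # exercise the tie-upward rule

    def prog(rt):
        us = rt.input_ring(0, u if rt.party == 0 else None, u.shape)
        vs = rt.input_ring(1, v if rt.party == 1 else None, v.shape)
        return rt.compare_ge(us, vs, 41)

    r0, r1 = two_party(prog)
    assert np.array_equal((r0 ^ r1).astype(bool), u >= v)


def test_mux_selects_plaintext_branch(two_party):
    rng = np.random.default_rng(13)
    c = rng.integers(0, 2, size=300).astype(np.uint8)
    x = rng.integers(0, 2 ** 30, size=300, dtype=np.uint64)
    y = rng.integers(0, 2 ** 30, size=300, dtype=np.uint64)

    def prog(rt):
        cs = rt.input_bits(0, c if rt.party == 0 else None, c.shape, np.uint8, 1)
        xs = rt.input_ring(0, x if rt.party == 0 else None, x.shape)
        ys = rt.input_ring(1, y if rt.party == 1 else None, y.shape)
        return rt.mux(cs, xs, ys)

    r0, r1 = two_party(prog)
    assert np.array_equal(r0 + r1, np.where(c == 1, x, y))


def test_divide_matches_floor_division(two_party):
    rng = np.random.default_rng(14)
    p = 16
    hw = rng.integers(0, 501, size=300, dtype=np.uint64)
    den = np.maximum(rng.integers(1, 1001, size=300, dtype=np.uint64), 2 * hw)

    def prog(rt):
        hs = rt.input_ring(0, hw if rt.party == 0 else None, hw.shape)
        ds = rt.input_ring(1, den if rt.party == 1 else None, den.shape)
        num = rt.a2b(hs, 9).astype(np.uint32) << np.uint32(p + 1)
        d = rt.a2b(ds, 10).astype(np.uint32)
        return rt.divide_packed(num, 9 + p + 1, d, p + 1, 11)

    r0, r1 = two_party(prog)
    got = (r0 ^ r1).astype(np.uint64)
    expected = (2 * hw.astype(object) << p) // den.astype(object)
    assert np.array_equal(got.astype(object), expected)


def test_eq_fold_equality_circuit(two_party):
    rng = np.random.default_rng(15)
    x = rng.integers(0, 2 ** 32, size=400, dtype=np.uint32)
    y = x.copy()
    y[::2] = rng.integers(0, 2 ** 32, size=200, dtype=np.uint32)

    def prog(rt):
        xs, ys = _shared_inputs(rt, x, y, np.uint32, 32)
        return _eq_fold(rt, xs ^ ys, 32)

    r0, r1 = two_party(prog)
    assert np.array_equal(((r0 ^ r1) & 1).astype(bool), x == y)


def test_reveal_counter_audits_reconstructions(two_party):
    def prog(rt):
        x = rt.input_ring(0, np.array([42], dtype=np.uint64) if rt.party == 0
                          else None, (1,))
        v = rt.reveal_ring(x)
        assert rt.reveal_count == 1
        return v

    r0, r1 = two_party(prog)
    assert r0[0] == r1[0] == 42


# -- privacy proxy: opened values are uniform, independent of the secret -----


def test_beaver_openings_uniform_for_both_secrets():
    """The opened value d = x ^ a is masked by a uniform triple component, so
    its distribution is the same whatever the secret bit is (sanity check on
    the transcript, not a security proof)."""
    n = 20_000
    b0, b1 = dealer_generate({"bool_u8": 2 * n, "b2a": 0, "arith": 0}, seed=77)
    a = b0.bool_pools["bool_u8"][0] ^ b1.bool_pools["bool_u8"][0]
    rng = np.random.default_rng(3)
    openings = {}
    for secret in (0, 1):
        x = np.full(n, secret, dtype=np.uint8)
        # share and mask as the AND gate does; collect the public opening
        x0 = rng.integers(0, 2, size=n, dtype=np.uint8)
        x1 = x ^ x0
        d = (x0 ^ x1) ^ a[secret * n:(secret + 1) * n] & np.uint8(1)
        openings[secret] = np.bincount(d & 1, minlength=2)
    for secret, counts in openings.items():
        assert stats.chisquare(counts).pvalue > 1e-3
    table = np.array([openings[0], openings[1]])
    assert stats.chi2_contingency(table).pvalue > 1e-3
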