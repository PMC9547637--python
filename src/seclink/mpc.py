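"""Full-threshold secret-sharing primitives and a two-party online engine.

Secrets are shared so that *all* shares are needed for reconstruction:

* Boolean sharing — a bit vector v is split into n shares with the first
  n-1 uniformly random and the last ``s_n = s_1 ^ ... ^ s_{n-1} ^ v``;
  XOR of shared values is local, AND is an interactive Beaver-triple
  protocol.
* Arithmetic sharing — the same construction on the ring Z_{2^l} with XOR
  replaced by subtraction: ``s_n = v - sum_i s_i  (mod 2^l)``; addition is
  local, multiplication uses arithmetic Beaver triples.

Correlated randomness (Beaver triples, bit-to-ring correlations) is produced
by a trusted dealer during an input-independent setup phase.  The original
system derives this material from oblivious transfer between the two
computation parties; the dealer preserves the correctness and the
setup/online structure of that design but is a genuine trust-model change —
a corrupted dealer colluding with one party breaks privacy.  See
docs/methods.md.

The online engine runs both parties as threads in one process, exchanging
numpy arrays over duplex queue channels.  Share containers are plain numpy
arrays: uint8 arrays holding single bits (values 0/1), unsigned integer
arrays holding bit-packed multi-bit words (bit j of element i is bit j of
the secret integer i), and uint64 arrays for ring elements.  All protocol
messages are masked openings, so a party's view consists of its own
(uniform) shares plus uniformly distributed opened values.
"""

from __future__ import annotations

import threading
from dataclasses import dataclass, field as dc_field
from queue import Empty, Queue
from typing import Callable, Optional

import numpy as np

MASK64 = (1 << 64) - 1


class MPCError(RuntimeError):
    pass


class ConsumableExhausted(MPCError):
    """A Beaver triple / correlation pool ran dry (or was not fully used)."""


class ChannelError(MPCError):
    pass


class ProtocolAbort(MPCError):
    """Pre-protocol consistency check failed (e.g. configuration mismatch)."""


def _bitmask(width: int, dtype):
    t = np.dtype(dtype).type
    return t(((1 << width) - 1) & np.iinfo(dtype).max)


def _packed_dtype(width: int):
    if width <= 8:
        return np.uint8
    if width <= 16:
        return np.uint16
    if width <= 32:
        return np.uint32
    if width <= 64:
        return np.uint64
    raise MPCError(f"width {width} exceeds 64 bits")


def _rand_uint(rng: np.random.Generator, shape, dtype) -> np.ndarray:
    info = np.iinfo(dtype)
    return rng.integers(0, int(info.max) + 1, size=shape, dtype=dtype)


def _rand_width(rng: np.random.Generator, shape, dtype, width: int) -> np.ndarray:
    out = _rand_uint(rng, shape, dtype)
    if width < np.iinfo(dtype).bits:
        out &= _bitmask(width, dtype)
    return out


# -- n-party sharing (full threshold) ----------------------------------------


def share_bits(value, n_parties: int, rng: np.random.Generator) -> list[np.ndarray]:
    """XOR-share a bit vector among ``n_parties`` (first n-1 shares uniform)."""
    if n_parties < 2:
        raise MPCError("need at least two parties")
    value = np.asarray(value)
    shares = [_rand_uint(rng, value.shape, value.dtype) for _ in range(n_parties - 1)]
    last = value.copy()
    for s in shares:
        last = last ^ s
    return shares + [last]


def reconstruct_bits(shares: list[np.ndarray]) -> np.ndarray:
    """XOR all shares together."""
    if not shares:
        raise MPCError("no shares")
    first = np.asarray(shares[0])
    out = first.copy()
    for s in shares[1:]:
        s = np.asarray(s)
        if s.shape != first.shape or s.dtype != first.dtype:
            raise MPCError("share width mismatch")
        out ^= s
    return out


def share_ring(value, n_parties: int, rng: np.random.Generator,
               ring_bits: int = 64) -> list[np.ndarray]:
    """Additively share integers on Z_{2^ring_bits}; last share is
    ``v - sum(others) mod 2^l``."""
    if n_parties < 2:
        raise MPCError("need at least two parties")
    value = np.asarray(value, dtype=np.uint64)
    mask = np.uint64(((1 << ring_bits) - 1) & MASK64)
    if ring_bits < 64 and np.any(value > mask):
        raise MPCError(f"value out of ring Z_2^{ring_bits}")
    shares = [_rand_uint(rng, value.shape, np.uint64) & mask for _ in range(n_parties - 1)]
    last = value.copy()
    for s in shares:
        last = (last - s) & mask
    return shares + [last]


def reconstruct_ring(shares: list[np.ndarray], ring_bits: int = 64) -> np.ndarray:
    mask = np.uint64(((1 << ring_bits) - 1) & MASK64)
    out = np.zeros_like(np.asarray(shares[0], dtype=np.uint64))
    for s in shares:
        out = (out + np.asarray(s, dtype=np.uint64)) & mask
    return out


# -- channels ----------------------------------------------------------------


class InProcChannel:
    """Ordered reliable duplex channel between two in-process parties.

    ``record_transcript=True`` keeps a copy of every received array (the
    party's protocol view) for the statistical privacy checks; it is off by
    default to bound memory.
    """

    def __init__(self, inbox: Queue, outbox: Queue, record_transcript: bool = False,
                 timeout: float = 600.0):
        self._inbox = inbox
        self._outbox = outbox
        self.record_transcript = record_transcript
        self.transcript: list[np.ndarray] = []
        self.bytes_sent = 0
        self.bytes_received = 0
        self.messages = 0
        self.timeout = timeout

    def send(self, arr: np.ndarray) -> None:
        arr = np.ascontiguousarray(arr)
        self.bytes_sent += arr.nbytes
        self._outbox.put(("msg", arr))

    def recv(self) -> np.ndarray:
        try:
            kind, payload = self._inbox.get(timeout=self.timeout)
        except Empty as exc:
            raise ChannelError("channel receive timed out") from exc
        if kind == "err":
            raise ChannelError(f"peer failed: {payload}")
        self.bytes_received += payload.nbytes
        self.messages += 1
        if self.record_transcript:
            self.transcript.append(payload.copy())
        return payload

    def fail(self, message: str) -> None:
        self._outbox.put(("err", message))


def make_channel_pair(record_transcript: bool = False) -> tuple[InProcChannel, InProcChannel]:
    q01: Queue = Queue()
    q10: Queue = Queue()
    return (InProcChannel(q10, q01, record_transcript),
            InProcChannel(q01, q10, record_transcript))


def run_pair(prog0: Callable, prog1: Callable,
             record_transcript: bool = False) -> tuple:
    """Run two party programs (each taking a channel) on concurrent threads."""
    ch0, ch1 = make_channel_pair(record_transcript)
    results: list = [None, None]
    errors: list = [None, None]

    def runner(i: int, prog: Callable, ch: InProcChannel) -> None:
        try:
            results[i] = prog(ch)
        except BaseException as exc:  # propagate to main thread
            errors[i] = exc
            ch.fail(repr(exc))

    threads = [threading.Thread(target=runner, args=(i, p, c), daemon=True)
               for i, (p, c) in enumerate(zip((prog0, prog1), (ch0, ch1)))]
    for t in threads:
        t.start()
    for t in threads:
        t.join()
    primary = [e for e in errors if e is not None and not isinstance(e, ChannelError)]
    if primary:
        raise primary[0]
    if any(errors):
        raise next(e for e in errors if e is not None)
    return results[0], results[1], (ch0, ch1)


# -- correlated-randomness dealer --------------------------------------------

_BOOL_POOLS = ("bool_u8", "bool_u16", "bool_u32", "bool_u64")
_POOL_DTYPES = {"bool_u8": np.uint8, "bool_u16": np.uint16,
                "bool_u32": np.uint32, "bool_u64": np.uint64}


@dataclass
class PartyBundle:
    """One party's correlated randomness for a protocol run (setup output).

    Pools are consumed strictly sequentially; a triple can never be reused
    and exhaustion raises.  ``assert_exhausted`` enforces that the online
    phase used exactly what the setup phase provisioned.
    """

    phase: str
    bool_pools: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]
    arith_pool: tuple[np.ndarray, np.ndarray, np.ndarray]
    b2a_pool: tuple[np.ndarray, np.ndarray]    # (r bit share uint8, r ring share uint64)
    b2a16_pool: tuple[np.ndarray, np.ndarray]  # narrow-ring variant (uint16 shares)
    _ptr: dict[str, int] = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        for key in list(self.bool_pools) + ["arith", "b2a", "b2a16"]:
            self._ptr.setdefault(key, 0)

    def _slice(self, key: str, arrays: tuple, count: int) -> tuple:
        start = self._ptr[key]
        if start + count > arrays[0].size:
            raise ConsumableExhausted(
                f"pool {key}: requested {count}, only {arrays[0].size - start} left")
        self._ptr[key] = start + count
        return tuple(a[start:start + count] for a in arrays)

    def take_bool(self, count: int, dtype) -> tuple:
        key = f"bool_u{np.iinfo(dtype).bits}"
        return self._slice(key, self.bool_pools[key], count)

    def take_arith(self, count: int) -> tuple:
        return self._slice("arith", self.arith_pool, count)

    def take_b2a(self, count: int) -> tuple:
        return self._slice("b2a", self.b2a_pool, count)

    def take_b2a16(self, count: int) -> tuple:
        return self._slice("b2a16", self.b2a16_pool, count)

    def consumed(self) -> dict[str, int]:
        return dict(self._ptr)

    def assert_exhausted(self) -> None:
        sizes = {k: v[0].size for k, v in self.bool_pools.items()}
        sizes["arith"] = self.arith_pool[0].size
        sizes["b2a"] = self.b2a_pool[0].size
        sizes["b2a16"] = self.b2a16_pool[0].size
        leftover = {k: sizes[k] - self._ptr[k] for k in sizes if sizes[k] != self._ptr[k]}
        if leftover:
            raise ConsumableExhausted(f"unconsumed correlated randomness: {leftover}")


class CountingBundle:
    """Dealer stub for the setup-phase tally pass: serves all-zero
    correlated randomness and records how much of each kind the (oblivious,
    hence input-independent) circuit consumes."""

    phase = "tally"

    def __init__(self) -> None:
        self.counts: dict[str, int] = {k: 0 for k in _BOOL_POOLS}
        self.counts["arith"] = 0
        self.counts["b2a"] = 0
        self.counts["b2a16"] = 0

    def take_bool(self, count: int, dtype) -> tuple:
        self.counts[f"bool_u{np.iinfo(dtype).bits}"] += count
        z = np.zeros(count, dtype=dtype)
        return z, z.copy(), z.copy()

    def take_arith(self, count: int) -> tuple:
        self.counts["arith"] += count
        z = np.zeros(count, dtype=np.uint64)
        return z, z.copy(), z.copy()

    def take_b2a(self, count: int) -> tuple:
        self.counts["b2a"] += count
        return np.zeros(count, dtype=np.uint8), np.zeros(count, dtype=np.uint64)

    def take_b2a16(self, count: int) -> tuple:
        self.counts["b2a16"] += count
        return np.zeros(count, dtype=np.uint8), np.zeros(count, dtype=np.uint16)

    def consumed(self) -> dict[str, int]:
        return dict(self.counts)

    def assert_exhausted(self) -> None:  # tally pass has nothing to exhaust
        return


class Dealer:
    """Trusted correlated-randomness dealer (setup phase only).

    Generates Boolean Beaver triples (c = a & b bitwise), arithmetic Beaver
    triples (c = a * b mod 2^64) and bit-to-ring correlations (a random bit
    shared both as XOR shares and as ring shares), split into two
    full-threshold party bundles.  No input-dependent work happens here.
    """

    def __init__(self, seed: int):
        self._rng = np.random.default_rng(seed)

    def generate(self, counts: dict[str, int]) -> tuple[PartyBundle, PartyBundle]:
        rng = self._rng
        bool_pools0: dict[str, tuple] = {}
        bool_pools1: dict[str, tuple] = {}
        for key in _BOOL_POOLS:
            n = counts.get(key, 0)
            dtype = _POOL_DTYPES[key]
            a0, a1, b0, b1, c0 = (_rand_uint(rng, n, dtype) for _ in range(5))
            c1 = ((a0 ^ a1) & (b0 ^ b1)) ^ c0
            bool_pools0[key] = (a0, b0, c0)
            bool_pools1[key] = (a1, b1, c1)
        n = counts.get("arith", 0)
        a0, a1, b0, b1, c0 = (_rand_uint(rng, n, np.uint64) for _ in range(5))
        c1 = (a0 + a1) * (b0 + b1) - c0
        arith0, arith1 = (a0, b0, c0), (a1, b1, c1)
        n = counts.get("b2a", 0)
        r0 = rng.integers(0, 2, size=n, dtype=np.uint8)
        r1 = rng.integers(0, 2, size=n, dtype=np.uint8)
        ra0 = _rand_uint(rng, n, np.uint64)
        ra1 = (r0 ^ r1).astype(np.uint64) - ra0
        n = counts.get("b2a16", 0)
        s0 = rng.integers(0, 2, size=n, dtype=np.uint8)
        s1 = rng.integers(0, 2, size=n, dtype=np.uint8)
        sa0 = _rand_uint(rng, n, np.uint16)
        sa1 = (s0 ^ s1).astype(np.uint16) - sa0
        return (PartyBundle("setup", bool_pools0, arith0, (r0, ra0), (s0, sa0)),
                PartyBundle("setup", bool_pools1, arith1, (r1, ra1), (s1, sa1)))


def dealer_generate(counts: dict[str, int], seed: int) -> tuple[PartyBundle, PartyBundle]:
    """Convenience wrapper: one-shot dealer invocation."""
    return Dealer(seed).generate(counts)


# -- two-party online runtime -------------------------------------------------


class PartyRuntime:
    """One party's view of the online protocol.

    Wraps the channel, the correlated-randomness bundle and a local RNG for
    input masking.  All methods operate elementwise on numpy arrays; Boolean
    shares are uint8 bits (0/1) or bit-packed unsigned words, arithmetic
    shares are uint64 (ring Z_{2^64}).
    """

    def __init__(self, party: int, channel: InProcChannel, bundle,
                 rng: np.random.Generator):
        if party not in (0, 1):
            raise MPCError("party must be 0 or 1")
        self.party = party
        self.channel = channel
        self.bundle = bundle
        self.rng = rng
        self.reveal_count = 0

    # -- messaging ---------------------------------------------------------

    def exchange(self, arr: np.ndarray) -> np.ndarray:
        self.channel.send(arr)
        return self.channel.recv()

    def open_xor(self, x: np.ndarray) -> np.ndarray:
        """Open a masked Boolean value (both parties learn x0 ^ x1)."""
        return x ^ self.exchange(x).reshape(x.shape)

    def open_add(self, x: np.ndarray) -> np.ndarray:
        """Open a masked ring value (both parties learn x0 + x1)."""
        return x + self.exchange(x).reshape(x.shape).astype(np.uint64)

    # -- input sharing -----------------------------------------------------

    def input_bits(self, owner: int, value: Optional[np.ndarray], shape, dtype,
                   width: int) -> np.ndarray:
        """Boolean-share an input held by ``owner``; the owner sends the
        uniform mask share and keeps value ^ mask."""
        if self.party == owner:
            mask = _rand_width(self.rng, shape, dtype, width)
            self.channel.send(mask)
            return value.astype(dtype) ^ mask
        return self.channel.recv().reshape(shape).astype(dtype)

    def input_ring(self, owner: int, value: Optional[np.ndarray], shape) -> np.ndarray:
        if self.party == owner:
            mask = _rand_uint(self.rng, shape, np.uint64)
            self.channel.send(mask)
            return value.astype(np.uint64) - mask
        return self.channel.recv().reshape(shape).astype(np.uint64)

    # -- boolean gates -------------------------------------------------------

    def and_bits(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Bitwise AND of two Boolean shares via one Beaver triple opening."""
        if x.shape != y.shape or x.dtype != y.dtype:
            raise MPCError("and_bits operand mismatch")
        a, b, c = self.bundle.take_bool(x.size, x.dtype)
        a, b, c = (t.reshape(x.shape) for t in (a, b, c))
        d_share = x ^ a
        e_share = y ^ b
        other = self.exchange(np.concatenate([d_share.ravel(), e_share.ravel()]))
        d = d_share ^ other[: x.size].reshape(x.shape)
        e = e_share ^ other[x.size:].reshape(x.shape)
        z = c ^ (d & b) ^ (e & a)
        if self.party == 0:
            z = z ^ (d & e)
        return z

    def not_bits(self, x: np.ndarray, width: int = 1) -> np.ndarray:
        """Local complement of the low ``width`` bits (party 0 flips)."""
        if self.party == 0:
            return x ^ _bitmask(width, x.dtype)
        return x.copy()

    def or_bits(self, x: np.ndarray, y: np.ndarray, width: int = 1) -> np.ndarray:
        return self.not_bits(self.and_bits(self.not_bits(x, width),
                                           self.not_bits(y, width)), width)

    # -- arithmetic gates ----------------------------------------------------

    def mul(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Ring multiplication of two arithmetic shares (Beaver opening)."""
        if x.shape != y.shape:
            raise MPCError("mul operand mismatch")
        a, b, c = self.bundle.take_arith(x.size)
        a, b, c = (t.reshape(x.shape) for t in (a, b, c))
        d_share = x - a
        e_share = y - b
        other = self.exchange(np.concatenate([d_share.ravel(), e_share.ravel()]))
        d = d_share + other[: x.size].reshape(x.shape)
        e = e_share + other[x.size:].reshape(x.shape)
        z = c + d * b + e * a
        if self.party == 0:
            z = z + d * e
        return z

    # -- conversions ---------------------------------------------------------

    def b2a(self, bits: np.ndarray) -> np.ndarray:
        """Convert single-bit Boolean shares (uint8, 0/1) to ring shares."""
        if bits.dtype != np.uint8:
            raise MPCError("b2a expects uint8 bit shares")
        r, ra = self.bundle.take_b2a(bits.size)
        r = r.reshape(bits.shape)
        ra = ra.reshape(bits.shape)
        z = self.open_xor(bits ^ r).astype(np.uint64)  # public bit x ^ r
        out = ra - np.uint64(2) * z * ra
        if self.party == 0:
            out = out + z
        return out

    def b2a16(self, bits: np.ndarray) -> np.ndarray:
        """b2a into the narrow ring Z_{2^16} (uint16 shares).

        Used for bounded bit sums such as Hamming weights, where the full
        64-bit ring would waste correlated-randomness memory."""
        if bits.dtype != np.uint8:
            raise MPCError("b2a16 expects uint8 bit shares")
        r, ra = self.bundle.take_b2a16(bits.size)
        r = r.reshape(bits.shape)
        ra = ra.reshape(bits.shape)
        z = self.open_xor(bits ^ r).astype(np.uint16)
        out = ra - np.uint16(2) * z * ra
        if self.party == 0:
            out = out + z
        return out

    def a2b(self, x: np.ndarray, width: int) -> np.ndarray:
        """Bit-decompose arithmetic shares: each party Boolean-shares its own
        ring share and a shared ripple-carry adder recombines them mod 2^width."""
        dtype = _packed_dtype(width)
        mask = np.uint64((1 << width) - 1) if width < 64 else np.uint64(MASK64)
        low = (x & mask).astype(dtype)
        xb0 = self.input_bits(0, low if self.party == 0 else None, x.shape, dtype, width)
        xb1 = self.input_bits(1, low if self.party == 1 else None, x.shape, dtype, width)
        s, _ = self.add_packed(xb0, xb1, width)
        return s

    # -- shared integer circuits ---------------------------------------------

    def add_packed(self, x: np.ndarray, y: np.ndarray, width: int,
                   carry_in: int = 0) -> tuple[np.ndarray, np.ndarray]:
        """Ripple-carry addition of bit-packed Boolean shares.

        One AND per full adder: c' = c ^ ((a^c) & (b^c)).  Returns (sum
        packed to ``width`` bits, carry-out bit shares)."""
        tt = x.dtype.type
        one = tt(1)
        one8 = np.uint8(1)
        c = np.full(x.shape, carry_in if self.party == 0 else 0, dtype=np.uint8)
        s = np.zeros(x.shape, dtype=x.dtype)
        for j in range(width):
            a = ((x >> tt(j)) & one).astype(np.uint8)
            b = ((y >> tt(j)) & one).astype(np.uint8)
            t = self.and_bits(a ^ c, b ^ c)
            s ^= (a ^ b ^ c).astype(x.dtype) << tt(j)
            # Beaver outputs carry uniform share bits above bit 0 (the secret
            # there is 0); mask to keep every wire a clean 0/1 share.
            c = (c ^ t) & one8
        return s, c

    def sub_packed(self, x: np.ndarray, y: np.ndarray,
                   width: int) -> tuple[np.ndarray, np.ndarray]:
        """x - y on ``width`` bits via x + ~y + 1; the carry-out is the
        no-borrow bit, i.e. shares of [x >= y]."""
        y_flip = y ^ _bitmask(width, y.dtype) if self.party == 0 else y
        return self.add_packed(x, y_flip, width, carry_in=1)

    def divide_packed(self, num: np.ndarray, num_bits: int, den: np.ndarray,
                      q_bits: int, r_bits: int) -> np.ndarray:
        """Restoring long division on bit-packed Boolean shares.

        Requires floor(num / den) < 2^q_bits and den < 2^(r_bits-1) (then the
        running remainder fits r_bits).  A zero denominator saturates the
        quotient to all ones; callers gate that case out.
        """
        tt = num.dtype.type
        rmask = _bitmask(r_bits, num.dtype)
        r = (num >> tt(q_bits)) & rmask  # top num_bits - q_bits bits; < den
        q = np.zeros(num.shape, dtype=num.dtype)
        for j in reversed(range(q_bits)):
            r = ((r << tt(1)) | ((num >> tt(j)) & tt(1))) & rmask
            diff, ge = self.sub_packed(r, den, r_bits)
            gmask = ge.astype(num.dtype) * rmask  # replicate decision bit across r_bits
            r = r ^ self.and_bits(r ^ diff, gmask)
            q ^= ge.astype(num.dtype) << tt(j)
        return q

    def compare_ge(self, u: np.ndarray, v: np.ndarray, bound_bits: int) -> np.ndarray:
        """Shares of [u >= v] for ring values known to satisfy u, v < 2^bound_bits.

        Computed as bit ``bound_bits`` of u - v + 2^bound_bits, extracted via
        bit decomposition; the bound is the caller's (configuration-derived)
        responsibility."""
        if bound_bits >= 63:
            raise MPCError("compare_ge bound must leave ring headroom")
        d = u - v
        if self.party == 0:
            d = d + np.uint64(1 << bound_bits)
        db = self.a2b(d, bound_bits + 1)
        tt = db.dtype.type
        return ((db >> tt(bound_bits)) & tt(1)).astype(np.uint8)

    def mux(self, c_bit: np.ndarray, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Oblivious select on arithmetic shares: x if c else y."""
        cb = self.b2a(c_bit)
        return y + self.mul(cb, x - y)

    def mux_ca(self, ca: np.ndarray, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """mux with an already-converted ring-share selector bit."""
        return y + self.mul(ca, x - y)

    # -- reconstruction ------------------------------------------------------

    def reveal_ring(self, x: np.ndarray, ring_bits: int = 64) -> np.ndarray:
        """Reconstruct an arithmetic secret towards both parties (audited)."""
        self.reveal_count += 1
        total = x + self.exchange(x).reshape(x.shape).astype(np.uint64)
        if ring_bits < 64:
            total = total & np.uint64((1 << ring_bits) - 1)
        return total

    def reveal_bits(self, x: np.ndarray) -> np.ndarray:
        self.reveal_count += 1
        return x ^ self.exchange(x).reshape(x.shape)
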