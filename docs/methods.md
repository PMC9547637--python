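# Methods

`seclink` computes how many patients two institutions have in common without
either institution disclosing identifying data, using fault-tolerant
(probabilistic) record linkage evaluated under two-party secret sharing.
This note documents the model, the parameters that matter, the numerical
choices, and what the synthetic-data experiments do and do not show.

## Record linkage model

Each record carries identifying fields (by default: first name, surname,
birth name, day/month/year of birth, ZIP code, city).  A record pair's
similarity is a normalised weighted sum of per-field similarities

    score(x, y) = Σ_{i ∈ D} w_i s_i / Σ_{i ∈ D} w_i ,

where `D` is the set of fields defined on both sides (missing fields drop
out of numerator *and* denominator), `s_i ∈ [0, 1]` is the field similarity
and `w_i > 0` the field weight.  Two thresholds classify the pair:
`score < t_tentative` → non-match, `score ≥ t_match` → match, in between →
tentative match.  Scores exactly at a threshold take the higher class.

**Field comparators.**  Exact fields (dates, ZIP) score 1 on token equality,
0 otherwise.  String fields are compared fuzzily: the normalised value is
split into overlapping bigrams, each bigram sets `k` bits of an `m`-bit
Bloom filter (double hashing of a keyed blake2b digest, indices
`(h1 + j·h2) mod m`), and the similarity is the Dice coefficient

    S = 2·Hw(Bl(x) ∧ Bl(y)) / (Hw(Bl(x)) + Hw(Bl(y))) ,

with `Hw` the Hamming weight.  A single-character substitution touches at
most two bigrams and therefore at most `2·2·k` filter bits, so small typos
produce proportionally small similarity drops — the property that makes the
linkage fault tolerant.  The Bloom filter is used purely as a similarity
data structure; privacy rests on the secret-sharing layer, and the hash
salt is public configuration shared by both parties.

**Weights.**  Unless set explicitly, `w_i = log2((1 − e_i)/f_i)` from the
field's error rate `e_i` (disagreement probability on true matches) and
frequency `f_i` (chance-agreement probability on non-matches) — the
standard log-likelihood-ratio weighting of probabilistic linkage.  The
packaged default rates (names `e=0.01, f=1e-4`; date parts `e=0.005`,
`f` = 1/support; ZIP `e=0.02, f=5e-4`; city `e=0.02, f=5e-3`) are
placeholders of realistic magnitude, not calibrated estimates; deployments
should fit them to their registries.  Default thresholds are 0.7/0.9,
default Bloom parameters `m=500`, `k=15`, bigrams, no padding sentinels.

**Exchange groups.**  First, sur- and birth name form an exchange group:
the group's values on one side are permuted against the fixed slots of the
other side, every permutation is scored, and the best total record score
wins.  Weights belong to slots (they encode the slot's error/frequency
statistics); missing slot pairs drop out per permutation.  Scoring is
symmetric: permuting either side yields the same maximum.

**Normalisation** (the cross-party contract): NFKD decomposition, removal
of combining marks, uppercasing, removal of non-alphanumeric characters,
whitespace collapsing; an empty result is ABSENT, which is distinct from
the empty string.  Both parties must normalise identically or the filters
diverge.

## Intersection cardinality

For datasets A and B, `match_count` is the number of A-records whose best
B-match classifies as MATCH (`tentative_count` analogously for the band
between the thresholds; the two are reported separately because study
protocols differ on whether tentatives count).  A record with several
matches counts once; an optional one-to-one greedy assignment mode exists
but is not the default.  The three-dataset overlap is computed by composing
two pairwise linkages (records of dataset 1 with a MATCH in both 2 and 3) —
the similarity is not transitive, so no direct three-way similarity is
attempted.

## Fixed-point arithmetic

The secure circuit works over the ring Z_{2^64}, so scores are integerised:
weights become `w̃_i = round(W·w_i)` (scale `W=256` by default), each field
similarity becomes `s_i^fp = floor(2^p · s_i)` with `p=16` fractional bits,
and a record accumulates the pair `(N, M) = (Σ w̃_i s_i^fp, Σ w̃_i)` over
defined fields.  Classification avoids division entirely:
`match ⇔ M ≥ 1 and N·t_den ≥ t_num·2^p·M` with the threshold as the exact
rational `t_num/t_den` of its decimal representation.  The exchange-group
maximum becomes a tournament on cross-multiplied ratios
(`N_a·M_b ≥ N_b·M_a`, challenger wins ties).  The `M ≥ 1` guard keeps the
degenerate all-fields-absent pair a non-match, mirroring the exact engine's
score-0 rule.

The worst-case error of the fixed-point score is below `fields · 2^-p`
(≈ 1.2e-4 for 8 fields), so classifications agree with the exact engine
whenever the exact score is farther than that from a threshold; the test
suite checks both the bound and the agreement.  Configuration loading
verifies that every intermediate product (tournament cross products,
threshold products) fits below `2^(ring_bits − 1)` and rejects
configurations that could wrap.

The plaintext engine implements this integer path a second time
(`mode="fixed"`), candidate order, tie rules and saturation behaviour
included, and serves as the bit-exact oracle for the circuit.

## Secure computation

Two-party full-threshold sharing: Boolean XOR shares for bits and
bit-packed words, additive shares mod 2^64 for ring values.  XOR/addition
are local; AND/multiplication consume Beaver triples; conversions `b2a`
(bit to ring, via a masked opening against a bit/ring-correlated random
bit) and `a2b` (ripple-carry addition of the two parties' Boolean-shared
ring shares, one AND per full adder) bridge the two forms.  Comparisons
extract an indicator bit of `u − v + 2^B` via `a2b`, where the bound `B` is
derived from the configuration at build time.  Division for the per-field
Dice quotient is a restoring long divider on Boolean shares (the running
remainder needs only `⌈log2(2m)⌉ + 1` bits; a zero denominator saturates
and is gated out by the presence bit).  The per-pair match bits are OR-ed
per left record (NOT-AND tree), converted, and summed; **only the two
aggregate counts are reconstructed**, which the runtime audits by counting
reveal operations (exactly two per run).

**Setup versus online.**  Correlated randomness is provisioned in an
input-independent setup phase: the circuit (whose control flow depends only
on sizes and configuration) is executed once on shape-identical zero
inputs against a counting stub, the dealer materialises exactly the
tallied pools, and the online phase must consume them to exhaustion —
over- or under-consumption raises.  Pools are consumed strictly
sequentially, so a triple can never be used twice.

**Trust model (important deviation).**  The original system derives its
correlated randomness from oblivious transfer between the two computation
parties, so no third party exists at all.  Here a *trusted dealer*
generates the triples: correctness and the setup/online structure are
preserved, but a dealer colluding with one party could break privacy.  The
dealer is acceptable for the correctness and accounting experiments this
package targets; it is not a deployment-grade replacement for OT.
Similarly, both parties run in one process over queue channels (semi-honest
model, no transport encryption), and the statistical "transcript looks
uniform regardless of the secret" test is a sanity check, not a security
proof.

## Synthetic data

The generator emulates the evaluation design of the real-world tests:
three datasets with `n` records each, `pairwise_overlap` persons shared by
exactly one pair of datasets (per pair), `triple_overlap` persons in all
three, the rest unique.  Identities are sampled from packaged name/city
pools (about 200 first names, 240 surnames, 120 cities), birth dates
uniform over 1920–2010 (days 1–28), uniform 5-digit ZIPs; distinctness is
enforced on (first name, surname, birth date).  At full scale the design
is ~18 000 records with ~200 pairwise and 8 triple overlaps; the package
default is 2 000 records with the same overlap counts, chosen so the full
recovery experiment runs on a single desk-scale core; the full size remains
a parameter away.

Corruption is applied only to duplicate *copies* (the canonical first
appearance stays clean, so ground truth is exact): per-field character
substitution, character deletion, field drop to ABSENT, and value swaps
inside an exchange group.  Default probabilities are a few percent per
field.  Corruption and row shuffling use independent RNG streams, so row
placement is identical across noise settings of the same seed.

What passing these experiments shows: the pipeline recovers a known
overlap structure exactly in the absence of noise, degrades gracefully
with noise, and the secure circuit is bit-exact against the plaintext
integer engine on realistic inputs.  What it does not show: linkage
quality on real registry data — real name/address distributions are far
more skewed than the uniform pools, real error processes are correlated
across fields, and the default weights are uncalibrated.  Precision/recall
on real data is a property of the configuration, not of this
implementation.

## Numerical and design notes

* Bloom filters are packed little-endian (bit `i` = byte `i//8`, bit
  `i%8`); bulk Dice popcounts use float32 BLAS matrix products of unpacked
  bit matrices (exact for counts < 2^24).
* The degenerate weight `log2((1−e)/f) = 0` at `(1−e) = f` is accepted by
  the weight function but rejected as a field weight (weights must be
  positive).
* Binary fields enter the circuit as 32-bit salted token hashes; a hash
  collision (probability 2^-32 per pair) could make the circuit call two
  differing tokens equal.  Plaintext modes compare tokens directly.
* Ties: thresholds and the permutation tournament resolve upward /
  challenger-wins consistently in the exact, fixed-point and secure paths.
* `link_pair` breaks best-match ties by the lowest right-hand index.
* The in-process channel is the only transport; the party programs are
  written against the channel interface, but no TCP transport is shipped.
* Sizes used by the shipped experiments: overlap recovery at 2 000 × 2 000
  per dataset pair (three pairs); secure/plaintext equivalence at 100 × 100
  with 10 planted noisy duplicates over five seeds; primitive suites at
  ≥ 10^3 randomized cases plus exhaustive small domains.

## Known limitations

* Two computation parties only; multi-party similarity is out of scope.
* Semi-honest security; no malicious-adversary protections.
* The correlated-randomness dealer replaces OT (see trust model above).
* All-pairs comparison (no blocking/indexing): cost is O(|A|·|B|).  In the
  secure path the correlated randomness provisioned during setup is also
  proportional to |A|·|B| (roughly 70 KB per record pair under the default
  configuration), so secure runs are desk-scale by design — about 100–200
  records per side within a few GB of memory.  The plaintext engine handles
  thousands of records per side.
* Default weights/thresholds are placeholders, flagged above.
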