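# seclink

Fault-tolerant, privacy-preserving record linkage and **patient intersection
cardinality**: how many patients do two institutions have in common, computed
without either side disclosing identifying data.

When studies pool patients across sites — especially for rare diseases, where
every site holds only a handful of cases and the same patient is often
registered at several of them — the first question is how large the overlap
between the sites' registries is.  Exact private-set-intersection protocols
answer it only for byte-identical identifiers, but real identifying data
(names, birth dates, addresses) carries typos, name changes and missing
fields.  `seclink` therefore links records *probabilistically* and evaluates
the linkage under secure two-party computation, revealing nothing but the
intersection counts.

## Method

Per record pair, field similarities are combined into a normalised weighted
sum over the fields defined on both sides,

    score(x, y) = Σ_i w_i s_i / Σ_i w_i ,            s_i ∈ [0, 1],

with log-likelihood weights `w_i = log2((1 − e_i)/f_i)` and two thresholds
(non-match / tentative match / match).  String fields are compared via the
Dice coefficient of bigram Bloom filters,

    S = 2·Hw(Bl(x) ∧ Bl(y)) / (Hw(Bl(x)) + Hw(Bl(y))) ,

so a one-letter typo changes at most `2k` filter bits and the similarity
degrades gracefully.  The three name fields form an *exchange group*: all
permutations are scored and the best one counts, tolerating swapped
first/sur/birth names.

The secure path runs the same scoring as an oblivious circuit over
full-threshold secret shares (Boolean XOR sharing with Beaver-triple ANDs,
additive sharing mod 2^64, share conversions, a restoring-division circuit
for the fixed-point Dice quotient and division-free threshold comparisons).
Each party sees only its own records, uniformly masked protocol messages and
the final two counts — per-pair match decisions are never reconstructed.
Correlated randomness comes from a trusted dealer in an input-independent
setup phase (a documented trust-model simplification relative to oblivious
transfer; see `docs/methods.md`).

A plaintext engine with bit-identical integer arithmetic serves as the
oracle: on every tested input the secure circuit reproduces its counts
exactly.

## Worked example

Generate three overlapping synthetic datasets (120 records each, 15 persons
shared per dataset pair, 4 shared by all three, no noise), then count the
1–2 intersection in plain and in secure mode:

```sh
seclink gen-data --n 120 --pairwise 15 --triple 4 --seed 42 --outdir data
seclink count data/dataset_1.csv data/dataset_2.csv
seclink count data/dataset_1.csv data/dataset_2.csv --secure --seed 1
```

The plain run prints

```json
{
  "config_digest": "b7618ed4402bd89f69e130259dd449d33ca56f068266d2b7cc0a470a8ea9a78e",
  "match_count": 19,
  "mode": "plain",
  "n_left": 120,
  "n_right": 120,
  "seconds": 0.011,
  "tentative_count": 0
}
```

`match_count` = 19 is exactly the planted overlap: 15 persons shared by
datasets 1 and 2 alone plus the 4 persons present in all three.  The secure
run reveals the same counts and reports its phase statistics:

```json
{
  "match_count": 19,
  "mode": "secure",
  "online_stats": {"bytes": 385448800, "messages": 5488, "reveals": 2, "seconds": 1.5},
  "setup_stats": {"consumables": {"b2a16": 72000000, "bool_u8": 34632120, "...": 0}, "seconds": 6.3},
  "tentative_count": 0
}
```

`reveals: 2` is the audit that only the two aggregate counts were ever
reconstructed.  The consumable counts are the Beaver triples and share
conversions provisioned in the setup phase and fully consumed online; their
volume grows with `n_left · n_right`, so secure runs are desk-scale
(~100–200 records per side), while the plaintext engine links thousands of
records in seconds.

The same functionality is available as a library:

```python
import seclink as sl

cfg = sl.default_config()
a = sl.encode_records(sl.load_records("data/dataset_1.csv", cfg), cfg)
b = sl.encode_records(sl.load_records("data/dataset_2.csv", cfg), cfg)
sl.intersection_cardinality_plain(a, b, cfg)      # plaintext
sl.secure_intersection_cardinality(a, b, cfg, seed=1)  # two-party protocol
```

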