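from itertools import permutations

import numpy as np
import pytest

from seclink.config import LinkageConfig, FieldSpec
from seclink.encoding import (BloomFilter, EncodedField, EncodedRecord,
                              encode_records)
from seclink.linkage import (FixedPointParams, MatchClass, classify,
                             classify_fixed, field_similarity,
                             intersection_cardinality_plain, link_pair,
                             multiway_overlap, pairwise_classes_fixed,
                             record_similarity, record_similarity_fixed)
from seclink.synth import NoiseModel, corrupt_record, generate_population


def _binary_field(present=True, token="X"):
    return EncodedField(present=present, token=token if present else None)


def _dice_field(bits, present=True):
    if not present:
        return EncodedField(present=False)
    arr = np.array(bits, dtype=np.uint8)
    bf = BloomFilter(len(bits), 1, np.packbits(arr, bitorder="little"))
    return EncodedField(present=True, filter=bf, hw=bf.popcount())


def test_field_similarity_binary_and_missing():
    spec = FieldSpec(name="y", comparator="binary", weight=1.0)
    assert field_similarity(_binary_field(token="1980"), _binary_field(token="1980"),
                            spec) == 1.0
    assert field_similarity(_binary_field(token="1980"), _binary_field(token="1981"),
                            spec) == 0.0
    dspec = FieldSpec(name="d", comparator="dice", weight=1.0)
    assert field_similarity(_dice_field([1, 0, 1]), _dice_field([], present=False),
                            dspec) is None


def _mini_config():
    return LinkageConfig(fields=(
        FieldSpec(name="f1", comparator="binary", weight=2.0),
        FieldSpec(name="f2", comparator="dice", weight=1.0, bloom_len=8, num_hashes=1),
        FieldSpec(name="f3", comparator="binary", weight=1.0),
    ))


def test_record_similarity_weighted_sum_with_missing():
    # weights (2, 1), similarities (1.0, 0.4), third field missing -> 0.8
    cfg = _mini_config()
    x = EncodedRecord(fields={
        "f1": _binary_field(token="A"),
        "f2": _dice_field([1, 1, 0, 0, 0, 0, 0, 0]),
        "f3": _binary_field(present=False),
    })
    y = EncodedRecord(fields={
        "f1": _binary_field(token="A"),
        "f2": _dice_field([1, 0, 1, 1, 0, 0, 0, 0]),  # dice = 2*1/(2+3) = 0.4
        "f3": _binary_field(token="B"),
    })
    assert record_similarity(x, y, cfg).value == pytest.approx(0.8)


def test_record_similarity_identity_and_symmetry(cfg):
    recs = encode_records(generate_population(12, seed=9, config=cfg), cfg)
    rng = np.random.default_rng(0)
    noisy = encode_records(
        [corrupt_record(r, NoiseModel(0.3, 0.2, 0.3, 0.2), rng, cfg)
         for r in generate_population(12, seed=9, config=cfg)], cfg)
    for x in recs[:4]:
        assert record_similarity(x, x, cfg).value == pytest.approx(1.0)
    for x, y in zip(recs, noisy):
        assert record_similarity(x, y, cfg).value == \
            pytest.approx(record_similarity(y, x, cfg).value, abs=1e-12)


def _swap_names(rec, a, b):
    out = EncodedRecord(fields=dict(rec.fields))
    out.fields[a], out.fields[b] = rec.fields[b], rec.fields[a]
    return out


def test_exchange_group_recovers_swapped_names(cfg):
    recs = encode_records(generate_population(6, seed=3, config=cfg), cfg)
    for rec in recs:
        swapped = _swap_names(rec, "first_name", "surname")
        assert record_similarity(rec, swapped, cfg).value == pytest.approx(1.0)


def test_exchange_group_equals_bruteforce_permutation_oracle(cfg):
    """Independent oracle: enumerate permutations and weighted sums directly."""
    group = cfg.exchange_groups[0]
    recs = encode_records(generate_population(10, seed=5, config=cfg), cfg)
    rng = np.random.default_rng(1)
    others = encode_records(
        [corrupt_record(r, NoiseModel(0.4, 0.2, 0.5, 0.3), rng, cfg)
         for r in generate_population(10, seed=5, config=cfg)], cfg)

    def brute(x, y):
        best = None
        for perm in permutations(range(len(group))):
            num = den = 0.0
            for spec in cfg.non_group_fields:
                s = field_similarity(x.fields[spec.name], y.fields[spec.name], spec)
                if s is not None:
                    num += spec.weight_value * s
                    den += spec.weight_value
            for slot, src in enumerate(perm):
                spec = cfg.field_map[group[slot]]
                s = field_similarity(x.fields[group[slot]], y.fields[group[src]], spec)
                if s is not None:
                    num += spec.weight_value * s
                    den += spec.weight_value
            score = num / den if den else 0.0
            best = score if best is None else max(best, score)
        return best

    for x, y in zip(recs, others):
        assert record_similarity(x, y, cfg).value == pytest.approx(brute(x, y),
                                                                   abs=1e-12)


@pytest.mark.parametrize("score,expected", [
    (0.5, MatchClass.NON_MATCH),
    (0.8, MatchClass.TENTATIVE_MATCH),
    (0.9, MatchClass.MATCH),   # tie resolves upward
    (0.7, MatchClass.TENTATIVE_MATCH),
    (0.699999, MatchClass.NON_MATCH),
])
def test_classify_thresholds(score, expected, cfg):
    assert classify(score, cfg) is expected


def test_link_pair_basics(cfg):
    recs = encode_records(generate_population(8, seed=6, config=cfg), cfg)
    best = link_pair(recs[:1], recs[:1], cfg)
    assert best[0].index == 0 and best[0].score == pytest.approx(1.0)
    assert best[0].match_class is MatchClass.MATCH
    # unrelated records stay below the tentative threshold
    other = encode_records(generate_population(8, seed=600, config=cfg), cfg)
    for bm in link_pair(recs, other, cfg):
        assert bm.match_class is MatchClass.NON_MATCH


def test_link_pair_invariant_under_permutation_of_right(cfg):
    recs = encode_records(generate_population(10, seed=8, config=cfg), cfg)
    targets = encode_records(generate_population(10, seed=8, config=cfg), cfg)
    perm = list(np.random.default_rng(2).permutation(10))
    shuffled = [targets[i] for i in perm]
    base = link_pair(recs, targets, cfg)
    moved = link_pair(recs, shuffled, cfg)
    for b, m in zip(base, moved):
        assert m.index == perm.index(b.index)
        assert m.score == pytest.approx(b.score)


def test_bulk_engine_matches_per_record_reference(cfg):
    pop = generate_population(15, seed=12, config=cfg)
    rng = np.random.default_rng(3)
    noisy = [corrupt_record(r, NoiseModel(), rng, cfg) for r in pop]
    A = encode_records(pop, cfg)
    B = encode_records(noisy[5:] + generate_population(5, seed=77, config=cfg), cfg)
    best = link_pair(A, B, cfg)
    for i in range(len(A)):
        scores = [record_similarity(A[i], B[j], cfg).value for j in range(len(B))]
        j = int(np.argmax(scores))
        assert best[i].index == j
        assert best[i].score == pytest.approx(scores[j], abs=1e-12)


def test_fixed_bulk_matches_per_record_fixed(cfg):
    fpp = FixedPointParams.from_config(cfg)
    pop = generate_population(10, seed=21, config=cfg)
    rng = np.random.default_rng(4)
    noisy = [corrupt_record(r, NoiseModel(0.1, 0.05, 0.2, 0.1), rng, cfg)
             for r in pop]
    A, B = encode_records(pop, cfg), encode_records(noisy, cfg)
    is_match, is_tom = pairwise_classes_fixed(A, B, cfg, fpp)
    for i in range(10):
        for j in range(10):
            n, m = record_similarity_fixed(A[i], B[j], cfg, fpp)
            c = classify_fixed(n, m, fpp)
            assert is_match[i, j] == (c is MatchClass.MATCH)
            assert is_tom[i, j] == (c is not MatchClass.NON_MATCH)


def test_intersection_counts_planted_duplicates(cfg):
    A = generate_population(100, seed=31, config=cfg)
    B = generate_population(100, seed=3100, config=cfg)
    B[:10] = A[:10]  # plant exact duplicates
    encA, encB = encode_records(A, cfg), encode_records(B, cfg)
    res = intersection_cardinality_plain(encA, encB, cfg)
    assert res.match_count == 10
    assert res.n_left == res.n_right == 100
    disjoint = intersection_cardinality_plain(
        encA, encode_records(generate_population(50, seed=999, config=cfg), cfg), cfg)
    assert disjoint.match_count == 0 and disjoint.tentative_count == 0


def test_match_count_monotone_in_threshold(cfg):
    pop = generate_population(40, seed=41, config=cfg)
    rng = np.random.default_rng(5)
    noisy = [corrupt_record(r, NoiseModel(0.15, 0.1, 0.1, 0.15), rng, cfg)
             for r in pop]
    encA, encB = encode_records(pop, cfg), encode_records(noisy, cfg)
    counts = []
    for tm in (0.75, 0.85, 0.95, 0.99):
        c = LinkageConfig(**{**cfg.model_dump(), "threshold_match": tm})
        counts.append(intersection_cardinality_plain(encA, encB, c).match_count)
    assert all(a >= b for a, b in zip(counts, counts[1:]))


def test_fixed_point_matches_exact_away_from_boundaries(cfg):
    fpp = FixedPointParams.from_config(cfg)
    nfields = len(cfg.fields)
    tol = nfields * 2.0 ** -fpp.p
    pop = generate_population(15, seed=51, config=cfg)
    rng = np.random.default_rng(6)
    noisy = [corrupt_record(r, NoiseModel(0.1, 0.1, 0.1, 0.1), rng, cfg)
             for r in pop]
    A, B = encode_records(pop, cfg), encode_records(noisy, cfg)
    for x, y in zip(A, B):
        exact = record_similarity(x, y, cfg).value
        n, m = record_similarity_fixed(x, y, cfg, fpp)
        approx = n / m / 2 ** fpp.p if m else 0.0
        assert abs(approx - exact) < tol
        for thr in (cfg.threshold_tentative, cfg.threshold_match):
            if abs(exact - thr) <= tol:
                break
        else:
            assert classify_fixed(n, m, fpp) is classify(exact, cfg)


def test_multiway_overlap_edges(cfg):
    one = encode_records(generate_population(1, seed=61, config=cfg), cfg)
    assert multiway_overlap(one, one, one, cfg) == 1
    other = encode_records(generate_population(4, seed=62, config=cfg), cfg)
    some = encode_records(generate_population(4, seed=63, config=cfg), cfg)
    assert multiway_overlap(one, one, other, cfg) == 0
    assert multiway_overlap(some, some, some, cfg) == 4


def test_all_fields_missing_scores_zero(cfg):
    empty = EncodedRecord(fields={n: EncodedField(present=False)
                                  for n in cfg.field_names})
    full = encode_records(generate_population(1, seed=71, config=cfg), cfg)[0]
    assert record_similarity(empty, full, cfg).value == 0.0
    fpp = FixedPointParams.from_config(cfg)
    n, m = record_similarity_fixed(empty, full, cfg, fpp)
    assert (n, m) == (0, 0)
    assert classify_fixed(n, m, fpp) is MatchClass.NON_MATCH
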