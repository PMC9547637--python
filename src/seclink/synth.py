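"""Synthetic patient datasets with controlled overlap and corruption.

Real patient identifying data cannot be redistributed, so every stage of the
pipeline is exercised on generated identities: names sampled from packaged
word pools, uniform birth dates, five-digit ZIP codes and a city pool.  The
three-dataset overlap design mirrors the evaluation layout of the original
study: three datasets of equal size, a configurable number of persons shared
by exactly one pair of datasets (per pair), and a small set of persons
present in all three — at full scale roughly 18 000 records per dataset,
around 200 exclusive pairwise overlaps and 8 triple overlaps; the package
default is a desk-scale 2 000 records per dataset with the same overlap
counts.

Corruption (typos, character deletions, swapped name fields, dropped fields)
is applied only to the *copies* of a person in later datasets, never to the
canonical first appearance, so ground truth stays exact and fault tolerance
can be measured against it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from importlib.resources import files
from pathlib import Path
from typing import Optional

import numpy as np

from .config import (ABSENT, LinkageConfig, PatientRecord, default_config,
                     write_records)

_ALPHABET = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
_DIGITS = "0123456789"


def _pool(name: str) -> list[str]:
    text = files("seclink.data").joinpath(name).read_text(encoding="utf-8")
    return [line.strip() for line in text.splitlines() if line.strip()]


@dataclass(frozen=True)
class DatasetComposition:
    """Three-dataset overlap design.

    ``pairwise_overlap`` persons are shared by *exactly* one pair of datasets
    (per unordered pair), ``triple_overlap`` persons by all three; the rest
    of each dataset is unique to it.
    """

    n_per_dataset: int = 2000
    pairwise_overlap: int = 200
    triple_overlap: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pairwise_overlap < 0 or self.triple_overlap < 0:
            raise ValueError("overlap counts must be nonnegative")
        if self.n_per_dataset < 2 * self.pairwise_overlap + self.triple_overlap + 1:
            raise ValueError(
                f"infeasible composition: need n >= 2*pairwise + triple + 1 = "
                f"{2 * self.pairwise_overlap + self.triple_overlap + 1}, "
                f"got {self.n_per_dataset}")


@dataclass(frozen=True)
class NoiseModel:
    """Per-field corruption probabilities applied to duplicate copies.

    ``p_substitute`` replaces one character, ``p_delete`` removes one,
    ``p_drop`` blanks the field to ABSENT; ``p_swap`` exchanges the values of
    two random members of an exchange group (once per group).  Defaults are
    the package's mild-noise profile (a few percent per field, the order of
    real-world typo and change rates)."""

    p_substitute: float = 0.02
    p_delete: float = 0.01
    p_swap: float = 0.01
    p_drop: float = 0.03

    def __post_init__(self) -> None:
        for name in ("p_substitute", "p_delete", "p_swap", "p_drop"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be a probability, got {v}")

    @classmethod
    def off(cls) -> "NoiseModel":
        return cls(0.0, 0.0, 0.0, 0.0)


@dataclass
class GroundTruth:
    """Person-id -> list of (dataset index, row index) placements."""

    placements: dict[int, list[tuple[int, int]]] = dc_field(default_factory=dict)

    def _datasets_of(self, pid: int) -> set[int]:
        return {ds for ds, _ in self.placements[pid]}

    def triple_count(self) -> int:
        return sum(1 for pid in self.placements if len(self._datasets_of(pid)) == 3)

    def pair_shared_count(self, i: int, j: int) -> int:
        """Persons present in both datasets i and j (includes triple overlap)."""
        return sum(1 for pid in self.placements
                   if {i, j} <= self._datasets_of(pid))

    def exclusive_pair_count(self, i: int, j: int) -> int:
        """Persons present in exactly datasets i and j."""
        return sum(1 for pid in self.placements
                   if self._datasets_of(pid) == {i, j})

    def to_json(self) -> str:
        return json.dumps({str(k): sorted(v) for k, v in self.placements.items()})

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        data = json.loads(text)
        return cls({int(k): [tuple(x) for x in v] for k, v in data.items()})


def generate_population(n: int, seed: int,
                        config: Optional[LinkageConfig] = None) -> list[PatientRecord]:
    """``n`` distinct synthetic persons, deterministic per seed.

    Distinctness is enforced on (first name, surname, full birth date), so a
    noise-free population contains no accidental duplicates.  Birth names
    equal the surname for most persons and differ for a minority (marriages).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    config = config or default_config()
    rng = np.random.default_rng(seed)
    first_pool = _pool("first_names.txt")
    sur_pool = _pool("surnames.txt")
    city_pool = _pool("cities.txt")
    records: list[PatientRecord] = []
    seen: set[tuple] = set()
    while len(records) < n:
        first = first_pool[rng.integers(len(first_pool))]
        sur = sur_pool[rng.integers(len(sur_pool))]
        day = int(rng.integers(1, 29))
        month = int(rng.integers(1, 13))
        year = int(rng.integers(1920, 2011))
        key = (first, sur, day, month, year)
        if key in seen:
            continue
        seen.add(key)
        birth = sur if rng.random() < 0.85 else sur_pool[rng.integers(len(sur_pool))]
        raw = {
            "first_name": first,
            "surname": sur,
            "birth_name": birth,
            "day_of_birth": str(day),
            "month_of_birth": str(month),
            "year_of_birth": str(year),
            "zip": f"{rng.integers(1000, 100000):05d}",
            "city": city_pool[rng.integers(len(city_pool))],
        }
        records.append(PatientRecord.from_raw(
            {name: raw.get(name, "") for name in config.field_names}, config))
    return records


def _mutate_string(value: str, rng: np.random.Generator, delete: bool) -> str:
    if not value:
        return value
    pos = int(rng.integers(len(value)))
    if delete:
        out = value[:pos] + value[pos + 1:]
        return out if out else value
    old = value[pos]
    pool = _DIGITS if old.isdigit() else _ALPHABET
    new = old
    while new == old:
        new = pool[rng.integers(len(pool))]
    return value[:pos] + new + value[pos + 1:]


def corrupt_record(record: PatientRecord, model: NoiseModel,
                   rng: np.random.Generator,
                   config: Optional[LinkageConfig] = None) -> PatientRecord:
    """Independent per-field application of the corruption operators."""
    config = config or default_config()
    values = dict(record.values)
    for group in config.exchange_groups:
        if len(group) >= 2 and rng.random() < model.p_swap:
            i, j = rng.choice(len(group), size=2, replace=False)
            a, b = group[int(i)], group[int(j)]
            values[a], values[b] = values[b], values[a]
    for name in config.field_names:
        if values[name] is ABSENT:
            continue
        if rng.random() < model.p_drop:
            values[name] = ABSENT
            continue
        if rng.random() < model.p_substitute:
            values[name] = _mutate_string(values[name], rng, delete=False)
        if rng.random() < model.p_delete:
            values[name] = _mutate_string(values[name], rng, delete=True)
    return PatientRecord(values=values)


def generate_overlapping_datasets(
    comp: DatasetComposition,
    noise: Optional[NoiseModel] = None,
    config: Optional[LinkageConfig] = None,
) -> tuple[list[list[PatientRecord]], GroundTruth]:
    """Three datasets realising the composition exactly, plus ground truth.

    The first (lowest-index) appearance of each person is the canonical
    record; later copies pass through :func:`corrupt_record`.  Rows are
    shuffled per dataset.
    """
    noise = noise or NoiseModel.off()
    config = config or default_config()
    n, pw, tr = comp.n_per_dataset, comp.pairwise_overlap, comp.triple_overlap
    unique_per_ds = n - 2 * pw - tr
    total = tr + 3 * pw + 3 * unique_per_ds
    persons = generate_population(total, seed=comp.seed, config=config)
    # independent streams so row placement does not depend on the noise model
    rng = np.random.default_rng(np.random.SeedSequence([comp.seed, 0xC0]))
    shuffle_rng = np.random.default_rng(np.random.SeedSequence([comp.seed, 0xC1]))

    memberships: list[tuple[int, tuple[int, ...]]] = []  # (person id, datasets)
    pid = 0
    for _ in range(tr):
        memberships.append((pid, (0, 1, 2)))
        pid += 1
    for pair in ((0, 1), (0, 2), (1, 2)):
        for _ in range(pw):
            memberships.append((pid, pair))
            pid += 1
    for ds in range(3):
        for _ in range(unique_per_ds):
            memberships.append((pid, (ds,)))
            pid += 1

    per_ds: list[list[tuple[int, PatientRecord]]] = [[], [], []]
    for person_id, datasets in memberships:
        canonical = persons[person_id]
        for rank, ds in enumerate(sorted(datasets)):
            rec = canonical if rank == 0 else corrupt_record(canonical, noise, rng, config)
            per_ds[ds].append((person_id, rec))

    datasets_out: list[list[PatientRecord]] = []
    gt = GroundTruth()
    for ds in range(3):
        order = shuffle_rng.permutation(len(per_ds[ds]))
        rows = [per_ds[ds][int(i)] for i in order]
        datasets_out.append([rec for _, rec in rows])
        for row_idx, (person_id, _) in enumerate(rows):
            gt.placements.setdefault(person_id, []).append((ds, row_idx))
    return datasets_out, gt


def write_datasets(datasets: list[list[PatientRecord]], gt: GroundTruth,
                   outdir: str | Path,
                   config: Optional[LinkageConfig] = None) -> list[Path]:
    """Emit the three CSVs and the ground-truth JSON; returns the CSV paths."""
    config = config or default_config()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, records in enumerate(datasets):
        path = outdir / f"dataset_{i + 1}.csv"
        write_records(records, path, config)
        paths.append(path)
    (outdir / "ground_truth.json").write_text(gt.to_json(), encoding="utf-8")
    return paths
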