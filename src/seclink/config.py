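"""Linkage configuration, field specifications and patient record ingestion.

The linkage configuration is the cross-party contract: both institutions must
normalise, encode and weight their identifying fields *identically* for the
similarity computation (and in particular the secure circuit) to be
meaningful.  Everything that influences an encoding therefore lives here:
field comparators, Bloom parameters, field weights (explicit or derived from
error/frequency statistics), exchange groups, classification thresholds and
the fixed-point parameters of the integer circuit.

Missing values are represented by :data:`ABSENT` (``None``), which is distinct
from the empty string: an empty or whitespace-only cell normalises to ABSENT.
"""

from __future__ import annotations

import json
import logging
import math
import re
import unicodedata
from dataclasses import dataclass, field as dc_field
from fractions import Fraction
from pathlib import Path
from typing import Literal, Optional

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, ValidationError, model_validator

logger = logging.getLogger(__name__)

#: Sentinel for a missing field value.  Distinct from the empty string.
ABSENT = None

_WS_RE = re.compile(r"\s+")


class ConfigurationError(ValueError):
    """Raised for invalid linkage configurations or malformed inputs."""


def normalize_value(raw: Optional[str]) -> Optional[str]:
    """Normalise a raw field value into the canonical cross-party form.

    Pipeline: Unicode compatibility decomposition (NFKD), removal of combining
    marks (so ``Ü`` → ``U``), uppercasing, removal of all characters that are
    neither alphanumeric nor an internal space, and whitespace collapsing.
    An empty result (including empty input) maps to :data:`ABSENT`.

    The function is total and idempotent; both parties must apply it before
    encoding so that identical identities yield bit-identical Bloom filters.
    """
    if raw is ABSENT:
        return ABSENT
    s = unicodedata.normalize("NFKD", str(raw))
    s = "".join(ch for ch in s if not unicodedata.combining(ch))
    s = s.upper()
    s = _WS_RE.sub(" ", s)
    s = "".join(ch for ch in s if ch.isalnum() or ch == " ")
    s = _WS_RE.sub(" ", s).strip()
    return s if s else ABSENT


def field_weight(error_rate: float, frequency: float) -> float:
    """Log-odds weight ``log2((1 - error_rate) / frequency)`` for a field.

    ``error_rate`` is the probability that the field disagrees on a true
    match (typos, outdated entries); ``frequency`` is the probability that it
    agrees by chance on a non-match (roughly the mean value frequency).  Rare,
    reliable fields (names) get large weights; coarse fields (month of birth)
    small ones.  Requires ``(1 - error_rate) / frequency > 1`` so the weight
    is positive.
    """
    if not (0.0 < error_rate < 1.0):
        raise ConfigurationError(f"error_rate must be in (0,1), got {error_rate}")
    if not (0.0 < frequency < 1.0):
        raise ConfigurationError(f"frequency must be in (0,1), got {frequency}")
    ratio = (1.0 - error_rate) / frequency
    if ratio < 1.0:
        raise ConfigurationError(
            f"(1-error_rate)/frequency = {ratio:.4g} is below 1; the weight "
            f"would be negative"
        )
    return math.log2(ratio)


class FieldSpec(BaseModel):
    """Specification of one identifying field.

    Exactly one of ``weight`` or the pair ``(error_rate, frequency)`` must be
    given; in the latter case the weight is derived via :func:`field_weight`.
    Bloom parameters apply to ``dice`` fields only.
    """

    model_config = ConfigDict(frozen=True)

    name: str
    comparator: Literal["dice", "binary"]
    weight: Optional[float] = None
    error_rate: Optional[float] = None
    frequency: Optional[float] = None
    bloom_len: int = 500   # m, bits
    num_hashes: int = 15   # k
    ngram_len: int = 2     # n
    padded: bool = False   # sentinel-padded n-grams (off: the filter mirrors interior bigrams only)

    @model_validator(mode="after")
    def _check(self) -> "FieldSpec":
        has_w = self.weight is not None
        has_ef = self.error_rate is not None and self.frequency is not None
        if has_w == has_ef:
            raise ValueError(
                f"field {self.name!r}: give exactly one of 'weight' or "
                f"('error_rate' and 'frequency')"
            )
        if has_w and not self.weight > 0:
            raise ValueError(f"field {self.name!r}: weight must be > 0")
        if has_ef and field_weight(self.error_rate, self.frequency) <= 0:
            raise ValueError(f"field {self.name!r}: derived weight must be > 0")
        if self.comparator == "dice":
            if self.bloom_len < 1 or self.num_hashes < 1 or self.ngram_len < 1:
                raise ValueError(f"field {self.name!r}: bloom parameters must be positive")
        return self

    @property
    def weight_value(self) -> float:
        """Effective weight: explicit if given, otherwise log-odds derived."""
        if self.weight is not None:
            return self.weight
        return field_weight(self.error_rate, self.frequency)


def _threshold_fraction(t: float) -> Fraction:
    """Exact rational form of a threshold, via its decimal representation."""
    return Fraction(str(t))


class LinkageConfig(BaseModel):
    """Full linkage configuration shared verbatim by both parties."""

    model_config = ConfigDict(frozen=True)

    fields: tuple[FieldSpec, ...]
    exchange_groups: tuple[tuple[str, ...], ...] = ()
    threshold_tentative: float = 0.7
    threshold_match: float = 0.9
    fixedpoint_bits: int = 16     # p: fractional bits of the integer score
    ring_bits: int = 64           # l: share ring Z_{2^l}
    weight_scale: int = 256       # W: weights rounded to integers after * W
    bloom_salt: str = "seclink/bloom/v1"
    token_salt: str = "seclink/token/v1"
    token_hash_bits: int = 32     # equality-hash width for binary fields in the circuit

    @model_validator(mode="after")
    def _check(self) -> "LinkageConfig":
        names = [f.name for f in self.fields]
        if not names:
            raise ValueError("at least one field is required")
        if len(set(names)) != len(names):
            raise ValueError("field names must be unique")
        if not (0.0 < self.threshold_tentative <= 1.0 and 0.0 < self.threshold_match <= 1.0):
            raise ValueError("thresholds must lie in (0, 1]")
        if self.threshold_tentative > self.threshold_match:
            raise ValueError(
                f"threshold_tentative ({self.threshold_tentative}) must not exceed "
                f"threshold_match ({self.threshold_match})"
            )
        seen: set[str] = set()
        by_name = {f.name: f for f in self.fields}
        for group in self.exchange_groups:
            if len(group) < 2:
                raise ValueError("exchange groups need at least two members")
            comps = set()
            for member in group:
                if member not in by_name:
                    raise ValueError(f"exchange group member {member!r} is not a configured field")
                if member in seen:
                    raise ValueError(f"field {member!r} appears in more than one exchange group")
                seen.add(member)
                comps.add(by_name[member].comparator)
            if len(comps) != 1:
                raise ValueError(f"exchange group {group} mixes comparators")
        if not (1 <= self.fixedpoint_bits <= 30):
            raise ValueError("fixedpoint_bits must be in [1, 30]")
        if not (8 <= self.ring_bits <= 64):
            raise ValueError("ring_bits must be in [8, 64]")
        if self.weight_scale < 1:
            raise ValueError("weight_scale must be positive")
        if not (8 <= self.token_hash_bits <= 64):
            raise ValueError("token_hash_bits must be in [8, 64]")
        self._check_ring_bounds()
        return self

    # -- derived quantities ------------------------------------------------

    @property
    def field_map(self) -> dict[str, FieldSpec]:
        return {f.name: f for f in self.fields}

    @property
    def field_names(self) -> list[str]:
        return [f.name for f in self.fields]

    def group_of(self, name: str) -> Optional[tuple[str, ...]]:
        for group in self.exchange_groups:
            if name in group:
                return group
        return None

    @property
    def non_group_fields(self) -> list[FieldSpec]:
        grouped = {m for g in self.exchange_groups for m in g}
        return [f for f in self.fields if f.name not in grouped]

    def scaled_weight(self, spec: FieldSpec) -> int:
        """Integerised weight round(W * w); guaranteed >= 1."""
        w = round(self.weight_scale * spec.weight_value)
        return max(int(w), 1)

    @property
    def scaled_weight_sum(self) -> int:
        return sum(self.scaled_weight(f) for f in self.fields)

    def threshold_fractions(self) -> tuple[Fraction, Fraction]:
        """(tentative, match) thresholds as exact rationals."""
        return (
            _threshold_fraction(self.threshold_tentative),
            _threshold_fraction(self.threshold_match),
        )

    def _check_ring_bounds(self) -> None:
        """Refuse configurations whose integer circuit could wrap the ring.

        Worst-case magnitudes: score numerator N <= (sum w~) * 2^p, weight
        mass M <= sum w~.  The circuit compares cross products N_a*M_b and
        threshold products N*t_den vs t_num*2^p*M; all must stay below
        2^(l-1) with headroom for the comparison offset bit.
        """
        p = self.fixedpoint_bits
        wsum = self.scaled_weight_sum
        bits_m = wsum.bit_length()
        bits_n = p + bits_m
        t_t, t_m = self.threshold_fractions()
        bits_tden = max(t_t.denominator, t_m.denominator).bit_length()
        bits_tnum = max(t_t.numerator, t_m.numerator).bit_length()
        worst = max(
            bits_n + bits_m,                 # tournament cross products
            bits_n + bits_tden,              # classification LHS
            bits_tnum + p + bits_m,          # classification RHS
        )
        if worst + 2 >= self.ring_bits:
            raise ValueError(
                f"fixed-point overflow risk: worst-case intermediate needs "
                f"{worst + 2} bits but ring has {self.ring_bits} "
                f"(reduce fixedpoint_bits, weight_scale or field weights)"
            )


@dataclass
class PatientRecord:
    """One person's identifying fields, already normalised.

    ``values`` maps every configured field name to a normalised string or
    :data:`ABSENT`.
    """

    values: dict[str, Optional[str]] = dc_field(default_factory=dict)

    @classmethod
    def from_raw(cls, raw: dict[str, Optional[str]], config: LinkageConfig) -> "PatientRecord":
        return cls(values={name: normalize_value(raw.get(name)) for name in config.field_names})

    def get(self, name: str) -> Optional[str]:
        return self.values[name]


# -- loading -----------------------------------------------------------------


def _build_config(data: dict) -> LinkageConfig:
    try:
        return LinkageConfig(**data)
    except ValidationError as exc:
        raise ConfigurationError(str(exc)) from exc


def load_config(path: str | Path) -> LinkageConfig:
    """Load and validate a linkage configuration from JSON or YAML."""
    path = Path(path)
    try:
        text = path.read_text(encoding="utf-8")
    except OSError as exc:
        raise ConfigurationError(f"cannot read config {path}: {exc}") from exc
    try:
        if path.suffix.lower() in (".yaml", ".yml"):
            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise ConfigurationError(f"cannot parse config {path}: {exc}") from exc
    if not isinstance(data, dict):
        raise ConfigurationError(f"config {path} must contain a mapping at top level")
    return _build_config(data)


def default_config() -> LinkageConfig:
    """The packaged 8-field configuration (three name fields form an exchange
    group).  The per-field error/frequency rates, and hence the weights, are
    documented placeholders — real deployments calibrate them per registry."""
    from importlib.resources import files

    text = files("seclink.data").joinpath("default_config.json").read_text(encoding="utf-8")
    return _build_config(json.loads(text))


def load_records(path: str | Path, config: LinkageConfig) -> list[PatientRecord]:
    """Read a patient CSV (UTF-8, RFC-4180, header row) into normalised records.

    Header names match configured field names case-insensitively.  Extra
    columns are ignored with a warning; a missing configured column is an
    error.  Row order is preserved.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    except OSError as exc:
        raise OSError(f"cannot read records {path}: {exc}") from exc
    except Exception as exc:  # malformed CSV
        raise ConfigurationError(f"cannot parse CSV {path}: {exc}") from exc
    colmap = {str(c).strip().lower(): c for c in df.columns}
    missing = [n for n in config.field_names if n.lower() not in colmap]
    if missing:
        raise ConfigurationError(f"CSV {path} is missing configured column(s): {missing}")
    extra = [c for c in df.columns if str(c).strip().lower() not in
             {n.lower() for n in config.field_names}]
    if extra:
        logger.warning("CSV %s: ignoring extra column(s) %s", path, extra)
    records = []
    for _, row in df.iterrows():
        raw = {name: row[colmap[name.lower()]] for name in config.field_names}
        records.append(PatientRecord.from_raw(raw, config))
    return records


def write_records(records: list[PatientRecord], path: str | Path,
                  config: LinkageConfig) -> None:
    """Write records to CSV (ABSENT as empty cell); inverse of load_records
    up to normalisation."""
    rows = [{name: (r.values[name] if r.values[name] is not ABSENT else "")
             for name in config.field_names} for r in records]
    pd.DataFrame(rows, columns=config.field_names).to_csv(path, index=False)


def config_digest(config: LinkageConfig) -> str:
    """Stable hash of the full configuration; exchanged in clear before a
    secure run so both parties abort on any mismatch."""
    import hashlib

    canonical = json.dumps(config.model_dump(), sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode("utf-8")).hexdigest()
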