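"""Shared domain types and field comparators.

The linkage pipeline moves person-level records through four stages
(standardize -> block -> deterministic cascade -> probabilistic scoring and
review).  The dataclasses here are the contracts between those stages: raw
registry/source rows, their standardized forms, declarative pass
specifications, and the per-record link decisions.
"""
from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "ConfigError",
    "MISSING",
    "AGREE",
    "DISAGREE",
    "MISSING_CMP",
    "LINKED_DETERMINISTIC",
    "LINKED_PROBABILISTIC",
    "LINKED_REVIEW",
    "UNLINKED",
    "COMPARATORS",
    "RegistryRecord",
    "SourceRecord",
    "StandardizedRecord",
    "BlockScheme",
    "FieldModel",
    "Thresholds",
    "PassSpec",
    "LinkDecision",
    "field_value",
    "compare_field",
    "hash_key",
]


class ConfigError(ValueError):
    """A configuration value is invalid; the message names the field."""


#: Canonical missing marker for identifier fields in CSV round-trips.
MISSING = ""

# Per-field comparison outcomes (Fellegi-Sunter comparison vector entries).
AGREE = "agree"
DISAGREE = "disagree"
MISSING_CMP = "missing"

# Final disposition statuses of a source record.
LINKED_DETERMINISTIC = "linked_deterministic"
LINKED_PROBABILISTIC = "linked_probabilistic"
LINKED_REVIEW = "linked_review"
UNLINKED = "unlinked"
LINKED_STATUSES = (LINKED_DETERMINISTIC, LINKED_PROBABILISTIC, LINKED_REVIEW)


@dataclass(frozen=True)
class RegistryRecord:
    """One row of the population registry (the reference file)."""

    key: str
    surname: str = MISSING
    given_names: str = MISSING
    sex: str = MISSING
    birth_date: str = MISSING       # ISO YYYY-MM-DD or ""
    coverage_start: str = MISSING
    last_contact: str = MISSING     # last contact with the covered system
    postal_code: str = MISSING


@dataclass(frozen=True)
class SourceRecord:
    """One row of an extract to be linked (immigration landing or death)."""

    source_id: str
    surname: str = MISSING
    given_names: str = MISSING
    sex: str = MISSING
    birth_date: str = MISSING
    event_date: str = MISSING       # landing date or death date
    postal_code: str = MISSING
    attrs: dict = field(default_factory=dict)


@dataclass
class StandardizedRecord:
    """A record after name cleaning, NYSIIS coding and city derivation.

    ``birth_year``/``month``/``day`` are kept as separate, individually
    missing-able parts: death registrations, in particular, may carry a
    partial date of birth.
    """

    rid: str
    surname_clean: str = ""
    given_clean: tuple[str, ...] = ()
    surname_nysiis: str = ""
    given_initial: str = ""
    birth_year: Optional[int] = None
    birth_month: Optional[int] = None
    birth_day: Optional[int] = None
    sex: str = ""                   # "F", "M" or "" (missing)
    city_code: str = "UNKNOWN"
    postal_code: str = ""
    event_date: Optional[dt.date] = None
    last_contact: Optional[dt.date] = None
    attrs: dict = field(default_factory=dict)

    @property
    def given_first(self) -> str:
        return self.given_clean[0] if self.given_clean else ""

    @property
    def birth_tuple(self) -> Optional[tuple[int, int, int]]:
        if None in (self.birth_year, self.birth_month, self.birth_day):
            return None
        return (self.birth_year, self.birth_month, self.birth_day)


@dataclass(frozen=True)
class BlockScheme:
    """Blocking keys partitioning both files into comparable subsets.

    ``missing_policy`` controls records missing a key field: ``own_block``
    groups them into a missing-valued block of their own (preserving the
    partition property), ``broadcast`` compares them against every block
    value of that field (used for missing sex, which would otherwise make a
    record unlinkable under sex stratification).
    """

    key_fields: tuple[str, ...]
    missing_policy: str = "own_block"

    def __post_init__(self):
        if not self.key_fields:
            raise ConfigError("block_scheme.key_fields must be nonempty")
        if len(set(self.key_fields)) != len(self.key_fields):
            raise ConfigError("block_scheme.key_fields contains duplicates")
        for f in self.key_fields:
            if f not in FIELD_NAMES:
                raise ConfigError(f"block_scheme.key_fields: unknown field {f!r}")
        if self.missing_policy not in ("own_block", "broadcast"):
            raise ConfigError(
                f"block_scheme.missing_policy: unknown policy {self.missing_policy!r}"
            )


@dataclass(frozen=True)
class FieldModel:
    """Agreement probabilities of one field under match (m) and non-match (u)."""

    field: str
    m: float
    u: float

    def validate(self) -> None:
        for name, p in (("m", self.m), ("u", self.u)):
            if not 0.0 < p < 1.0:
                raise ConfigError(
                    f"field_model[{self.field}].{name} must lie in (0,1), got {p}"
                )

    @property
    def informative(self) -> bool:
        return self.m > self.u


@dataclass(frozen=True)
class Thresholds:
    """Lower/upper decision thresholds on the total log2-odds weight (bits)."""

    t_lower: float
    t_upper: float

    def __post_init__(self):
        if self.t_lower > self.t_upper:
            raise ConfigError(
                f"thresholds: t_lower ({self.t_lower}) > t_upper ({self.t_upper})"
            )


@dataclass(frozen=True)
class PassSpec:
    """Declarative description of one linkage pass."""

    pass_id: int
    mode: str                                   # "deterministic" | "probabilistic"
    block_scheme: BlockScheme
    match_fields: tuple[tuple[str, str], ...]   # (field, comparator)
    thresholds: Optional[Thresholds] = None
    models: tuple[FieldModel, ...] = ()
    window_days: int = 30
    margin: float = 1.0                         # runner-up margin (bits)

    def __post_init__(self):
        if self.mode not in ("deterministic", "probabilistic"):
            raise ConfigError(f"pass {self.pass_id}: unknown mode {self.mode!r}")
        if not self.match_fields:
            raise ConfigError(f"pass {self.pass_id}: match_fields must be nonempty")
        for fld, cmp_ in self.match_fields:
            if fld not in FIELD_NAMES:
                raise ConfigError(f"pass {self.pass_id}: unknown field {fld!r}")
            if cmp_ not in COMPARATORS:
                raise ConfigError(f"pass {self.pass_id}: unknown comparator {cmp_!r}")
        if self.mode == "deterministic" and self.thresholds is not None:
            raise ConfigError(
                f"pass {self.pass_id}: deterministic passes take no thresholds"
            )
        if self.mode == "probabilistic":
            if self.thresholds is None:
                raise ConfigError(f"pass {self.pass_id}: probabilistic pass needs thresholds")
            have = {m.field for m in self.models}
            need = {f for f, _ in self.match_fields}
            if not need <= have:
                raise ConfigError(
                    f"pass {self.pass_id}: no field model for {sorted(need - have)}"
                )
            for m in self.models:
                m.validate()

    def model_for(self, fld: str) -> FieldModel:
        for m in self.models:
            if m.field == fld:
                return m
        raise ConfigError(f"pass {self.pass_id}: no field model for {fld!r}")


@dataclass
class LinkDecision:
    """Final disposition of one source record."""

    source_id: str
    registry_key: Optional[str] = None
    status: str = UNLINKED
    pass_id: Optional[int] = None
    weight: Optional[float] = None

    @property
    def linked(self) -> bool:
        return self.status in LINKED_STATUSES


# ---------------------------------------------------------------------------
# Field access and comparators
# ---------------------------------------------------------------------------

FIELD_NAMES = (
    "sex",
    "surname_clean",
    "surname_nysiis",
    "given_first",
    "given_initial",
    "birth_year",
    "birth_month",
    "birth_day",
    "birth_date",
    "city_code",
    "event_date",
)


def field_value(rec: StandardizedRecord, name: str):
    """Value of a matchable/blockable field; ``None`` when missing."""
    if name == "birth_date":
        return rec.birth_tuple
    if name == "city_code":
        return None if rec.city_code in ("", "UNKNOWN") else rec.city_code
    v = getattr(rec, name)
    if v in ("", None):
        return None
    return v


def _cmp_equal(fld):
    def cmp(src: StandardizedRecord, reg: StandardizedRecord, window_days: int) -> str:
        a, b = field_value(src, fld), field_value(reg, fld)
        if a is None or b is None:
            return MISSING_CMP
        return AGREE if a == b else DISAGREE

    return cmp


def _cmp_date_transpose(src, reg, window_days):
    a, b = src.birth_tuple, reg.birth_tuple
    if a is None or b is None:
        return MISSING_CMP
    if a == b:
        return AGREE
    ya, ma, da = a
    yb, mb, db = b
    if ya == yb and ma == db and da == mb:
        return AGREE
    return DISAGREE


def _cmp_event_window(src, reg, window_days):
    if src.event_date is None or reg.last_contact is None:
        return MISSING_CMP
    delta = abs((src.event_date - reg.last_contact).days)
    return AGREE if delta <= window_days else DISAGREE


class _Comparator:
    """A named comparator with an optional hash canonicalization.

    ``canon`` maps a record to a hashable token such that two records agree
    under the comparator iff their tokens are equal and non-None; comparators
    without such a token (``event_within_window``) force block-scan matching.
    """

    def __init__(self, name, func, field=None, canon=None):
        self.name = name
        self.func = func
        self.field = field
        self.canon = canon

    def __call__(self, src, reg, window_days=30):
        return self.func(src, reg, window_days)


def _canon_field(fld):
    def canon(rec):
        return field_value(rec, fld)

    return canon


def _canon_transpose(rec):
    t = rec.birth_tuple
    if t is None:
        return None
    y, m, d = t
    return (y, min(m, d), max(m, d))


_TRANSPOSE_CMP = _Comparator(
    "date_transpose_tolerant", _cmp_date_transpose, "birth_date", _canon_transpose
)
_EVENT_WINDOW_CMP = _Comparator(
    "event_within_window", _cmp_event_window, "event_date", None
)

# Equality comparators resolve to a concrete field; the named variants exist
# so pass configurations read like the blocking/matching schemes they mirror.
_EQ_FIELD = {
    "nysiis_exact": "surname_nysiis",
    "year_exact": "birth_year",
    "date_exact": "birth_date",
}


def _bound_comparator(name: str, fld: str) -> _Comparator:
    """Comparator instance bound to a concrete field."""
    if name == "date_transpose_tolerant":
        return _TRANSPOSE_CMP
    if name == "event_within_window":
        return _EVENT_WINDOW_CMP
    if name == "exact":
        eff = fld
    elif name in _EQ_FIELD:
        eff = _EQ_FIELD[name]
    else:
        raise ConfigError(f"unknown comparator {name!r}")
    return _Comparator(name, _cmp_equal(eff), eff, _canon_field(eff))


#: Names of all supported comparators (for validation).
COMPARATORS = (
    "exact",
    "nysiis_exact",
    "year_exact",
    "date_exact",
    "date_transpose_tolerant",
    "event_within_window",
)


def compare_field(src, reg, fld: str, comparator: str, window_days: int = 30) -> str:
    """Outcome of comparing ``fld`` between a source and registry record."""
    return _bound_comparator(comparator, fld)(src, reg, window_days)


def hash_key(rec: StandardizedRecord, match_fields, window_days: int = 30):
    """Hashable agreement token over the pass's match fields.

    Returns None when the pass contains a non-hashable comparator or the
    record is missing a compared field (missing counts as disagreement in
    deterministic passes, so such a record can never link there).
    """
    parts = []
    for fld, cname in match_fields:
        comp = _bound_comparator(cname, fld)
        if comp.canon is None:
            return None
        v = comp.canon(rec)
        if v is None:
            return None
        parts.append(v)
    return tuple(parts)


def has_unhashable(match_fields) -> bool:
    return any(
        _bound_comparator(c, f).canon is None for f, c in match_fields
    )
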