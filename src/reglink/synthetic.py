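"""Ground-truthed synthetic registries and source extracts.

Real population registries and the immigration/death extracts linked to them
are confidential, so the linkage pipeline is exercised on synthetic files
that emulate their statistical structure rather than their content:

* a skewed surname distribution with an overlaid pool of very common short
  surnames (the subpopulation for which exact name agreement carries little
  identifying information and linkage is known to degrade);
* per-field corruption — typos, phonetic-equivalent respellings that keep
  the NYSIIS code, day/month transposition in birth dates, missing values;
* era-dependent data quality: a multiplier per event-year band scales every
  corruption rate, emulating older records being dirtier;
* a fraction of source records with no registry counterpart at all (e.g.
  early neonatal deaths never issued a registration number), which receive
  freshly invented identifiers so no accidental true match exists;
* within-source duplicates: some truth persons contribute two source
  records differing in event date.

Every source record's true registry key (or NONE) is returned in a
ground-truth map, making precision/recall computable downstream.  All
randomness flows from one configured seed, split into named substreams so
that adding a generator does not perturb the others.
"""
from __future__ import annotations

import calendar
import csv
import datetime as dt
import logging
import zlib
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

from ._names import GIVEN_NAMES, PHONETIC_VARIANTS, SHORT_SURNAME_POOL, SURNAMES
from .model import ConfigError, MISSING, RegistryRecord, SourceRecord

__all__ = [
    "SyntheticConfig",
    "GroundTruthMap",
    "generate_registry",
    "derive_source",
    "corrupt_field",
    "substream",
    "write_registry_csv",
    "write_source_csv",
    "write_truth_csv",
    "DEFAULT_ERA_QUALITY",
]

log = logging.getLogger(__name__)

#: Default era multipliers on the corruption rates, keyed by the start year
#: of a 5-year event band: older records are dirtier, emulating the steady
#: improvement of administrative data quality over time.  The curve is
#: steep enough that adjacent eras differ by several times the binomial
#: noise of the era series at the problem sizes the package typically runs.
DEFAULT_ERA_QUALITY = {1985: 4.0, 1990: 3.0, 1995: 2.2, 2000: 1.5, 2005: 1.0, 2010: 0.5}

# City -> postal prefix used when *generating* codes; the shipped toy
# conversion table inverts this with longest-prefix semantics (EASTERN owns
# the whole K region except the K1 Ottawa carve-out).
_CITY_PREFIX = (
    ("TORONTO", "M", 0.40),
    ("CENTRAL", "L", 0.25),
    ("SOUTHWEST", "N", 0.15),
    ("EASTERN", "K", 0.10),     # suffix digit 2-9 so K1 stays Ottawa's
    ("OTTAWA", "K1", 0.07),
    ("NORTHERN", "P", 0.03),
)

_IMMIGRANT_CLASSES = (
    ("Family Class", 0.34),
    ("Economic Immigrants", 0.48),
    ("Refugees/Asylum Seekers", 0.14),
    ("Other", 0.03),
    ("No categorization", 0.01),
)

_REGIONS_OTHER = (
    "Southern Asia", "Europe", "Africa", "Americas",
    "South East Asia", "West Central Asia and the Middle East",
)

_CAUSES = (
    ("Circulatory", 0.34), ("Neoplasms", 0.29), ("Respiratory", 0.085),
    ("External", 0.06), ("Digestive", 0.04), ("Endocrine", 0.04),
    ("Mental", 0.035), ("Nervous", 0.035), ("Infectious", 0.02),
    ("Congenital", 0.004), ("Perinatal", 0.005), ("Other", 0.141),
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator parameters; defaults define the standard study conditions."""

    n_registry: int = 1000
    n_source: int = 500
    kind: str = "immigration"               # "immigration" | "death"
    unlinkable_frac: float = 0.05
    dup_frac: float = 0.02
    typo_rate: float = 0.05
    phonetic_swap_rate: float = 0.03
    date_transpose_rate: float = 0.02
    missing_rate: float = 0.03
    common_surname_frac: float = 0.15
    common_pool: tuple[str, ...] = tuple(SHORT_SURNAME_POOL)
    era_quality: tuple[tuple[int, float], ...] = tuple(
        sorted(DEFAULT_ERA_QUALITY.items())
    )
    seed: int = 0
    birth_year_range: tuple[int, int] = (1930, 2005)
    event_year_range: Optional[tuple[int, int]] = None

    def validate(self) -> None:
        for name in ("n_registry", "n_source"):
            if int(getattr(self, name)) < 1:
                raise ConfigError(f"{name} must be >= 1")
        for name in (
            "unlinkable_frac", "dup_frac", "typo_rate", "phonetic_swap_rate",
            "date_transpose_rate", "missing_rate", "common_surname_frac",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0,1], got {v}")
        if self.kind not in ("immigration", "death"):
            raise ConfigError(f"kind must be immigration or death, got {self.kind!r}")
        if not self.common_pool:
            raise ConfigError("common_pool must be nonempty")
        for band, mult in self.era_quality:
            if mult < 0:
                raise ConfigError(f"era_quality[{band}] must be >= 0, got {mult}")
        if self.birth_year_range[0] > self.birth_year_range[1]:
            raise ConfigError("birth_year_range must be (lo, hi) with lo <= hi")

    @property
    def effective_event_years(self) -> tuple[int, int]:
        if self.event_year_range is not None:
            return self.event_year_range
        return (1985, 2012) if self.kind == "immigration" else (1990, 2012)

    def era_multiplier(self, year: int) -> float:
        bands = sorted(self.era_quality)
        mult = bands[0][1]
        for start, m in bands:
            if year >= start:
                mult = m
        return mult


class GroundTruthMap(dict):
    """source_id -> registry key, or None for structurally unlinkable records."""

    def write_csv(self, path) -> None:
        write_truth_csv(self, path)


def substream(seed: int, name: str) -> np.random.Generator:
    """Named RNG substream of the single configured seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode())])
    )


def _powerlaw_weights(n: int, s: float) -> np.ndarray:
    w = 1.0 / np.arange(1, n + 1) ** s
    return w / w.sum()

# Shallow power-law over the general list (many moderately common names);
# steep one over the short pool (a handful of names dominate).
_GENERAL_W = _powerlaw_weights(len(SURNAMES), 0.6)
_GIVEN_W = _powerlaw_weights(len(GIVEN_NAMES), 0.9)


def _random_date(rng, y0: int, y1: int) -> dt.date:
    year = int(rng.integers(y0, y1 + 1))
    month = int(rng.integers(1, 13))
    day = int(rng.integers(1, calendar.monthrange(year, month)[1] + 1))
    return dt.date(year, month, day)


def _postal(rng) -> str:
    cities, prefixes, weights = zip(*_CITY_PREFIX)
    i = int(rng.choice(len(cities), p=np.array(weights) / sum(weights)))
    prefix = prefixes[i]
    letters = "BCDEFGHJKLMNPRSTVWXYZ"
    out = prefix
    if prefix == "K":                       # keep out of Ottawa's K1 carve-out
        out += str(rng.integers(2, 10))
    elif len(prefix) == 1:
        out += str(rng.integers(0, 10))
    # fill to the A1A1A1 shape
    while len(out) < 6:
        if len(out) % 2 == 0:
            out += letters[int(rng.integers(0, len(letters)))]
        else:
            out += str(rng.integers(0, 10))
    return out


def _surname(rng, cfg: SyntheticConfig) -> str:
    if rng.random() < cfg.common_surname_frac:
        pool_w = _powerlaw_weights(len(cfg.common_pool), 1.2)
        return cfg.common_pool[int(rng.choice(len(cfg.common_pool), p=pool_w))]
    return SURNAMES[int(rng.choice(len(SURNAMES), p=_GENERAL_W))]


def _given(rng) -> str:
    name = GIVEN_NAMES[int(rng.choice(len(GIVEN_NAMES), p=_GIVEN_W))]
    if rng.random() < 0.3:
        name += " " + GIVEN_NAMES[int(rng.choice(len(GIVEN_NAMES), p=_GIVEN_W))]
    return name


def generate_registry(config: SyntheticConfig) -> list[RegistryRecord]:
    """Generate ``n_registry`` registry persons, deterministic given the seed."""
    config.validate()
    rng = substream(config.seed, "registry")
    y0, y1 = config.birth_year_range
    ey0, ey1 = config.effective_event_years
    records = []
    seen_identities: set[tuple] = set()
    for i in range(config.n_registry):
        birth = _random_date(rng, y0, y1)
        coverage = max(birth, _random_date(rng, max(y0, 1970), ey0))
        last_contact = _random_date(rng, ey0, ey1 + 1)
        if last_contact < coverage:
            last_contact = coverage
        # registry persons are identity-distinct: two persons may share a
        # surname (the common-surname failure mode needs that) but never the
        # (surname, first given name, birth date, sex) tuple the matcher
        # sees, so ground truth is unambiguous and noise-free data is
        # perfectly linkable
        surname, given, sex = "", "", ""
        for _ in range(100):
            surname = _surname(rng, config)
            given = _given(rng)
            sex = "F" if rng.random() < 0.5 else "M"
            identity = (surname, given.split()[0], birth.isoformat(), sex)
            if identity not in seen_identities:
                seen_identities.add(identity)
                break
        records.append(
            RegistryRecord(
                key=f"R{i + 1:07d}",
                surname=surname,
                given_names=given,
                sex=sex,
                birth_date=birth.isoformat(),
                coverage_start=coverage.isoformat(),
                last_contact=last_contact.isoformat(),
                postal_code=_postal(rng),
            )
        )
    return records


# ---------------------------------------------------------------------------
# Field corruption operators
# ---------------------------------------------------------------------------

_VARIANT_LOOKUP: dict[str, list[str]] = {}
for _cls in PHONETIC_VARIANTS:
    for _name in _cls:
        _VARIANT_LOOKUP[_name] = [v for v in _cls if v != _name]

_ALPHABET = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


def _typo(value: str, rng) -> str:
    """One random edit (substitute/insert/delete/transpose); always changes."""
    if not value:
        return value
    for _ in range(20):
        op = rng.choice(["sub", "ins", "del", "swap"])
        chars = list(value)
        if op == "sub":
            i = int(rng.integers(0, len(chars)))
            c = _ALPHABET[int(rng.integers(0, 26))]
            if c == chars[i]:
                continue
            chars[i] = c
        elif op == "ins":
            i = int(rng.integers(0, len(chars) + 1))
            chars.insert(i, _ALPHABET[int(rng.integers(0, 26))])
        elif op == "del":
            if len(chars) <= 1:
                continue
            del chars[int(rng.integers(0, len(chars)))]
        else:
            if len(chars) < 2:
                continue
            i = int(rng.integers(0, len(chars) - 1))
            if chars[i] == chars[i + 1]:
                continue
            chars[i], chars[i + 1] = chars[i + 1], chars[i]
        out = "".join(chars)
        if out != value:
            return out
    return value + "X"      # pathological inputs: force a change


def corrupt_field(value: str, operator: str, rng: np.random.Generator) -> str:
    """Apply one corruption operator; inapplicable operators no-op with a warning.

    Operators: ``typo`` (one random edit), ``phonetic_swap`` (substitute a
    same-NYSIIS spelling variant from the shipped table), ``date_transpose``
    (swap day and month of an ISO date when the day is a valid month and
    differs from it), ``drop`` (missing marker).
    """
    if operator == "drop":
        return MISSING
    if operator == "typo":
        return _typo(value, rng)
    if operator == "phonetic_swap":
        variants = _VARIANT_LOOKUP.get(value.upper())
        if not variants:
            log.warning("phonetic_swap: no variant for %r; no-op", value)
            return value
        return variants[int(rng.integers(0, len(variants)))]
    if operator == "date_transpose":
        d = None
        try:
            d = dt.date.fromisoformat(value)
        except (TypeError, ValueError):
            pass
        if d is None or d.day > 12 or d.day == d.month:
            log.warning("date_transpose: inapplicable to %r; no-op", value)
            return value
        return dt.date(d.year, d.day, d.month).isoformat()
    raise ConfigError(f"unknown corruption operator {operator!r}")


def _maybe(rng, rate: float) -> bool:
    return rate > 0 and rng.random() < rate


def _corrupt_identifiers(rec: dict, mult: float, cfg: SyntheticConfig, rng) -> dict:
    """Apply each per-field operator independently at its era-scaled rate."""
    out = dict(rec)
    t, ps, dtr, ms = (
        cfg.typo_rate * mult,
        cfg.phonetic_swap_rate * mult,
        cfg.date_transpose_rate * mult,
        cfg.missing_rate * mult,
    )
    if out["surname"] and _maybe(rng, ps) and out["surname"].upper() in _VARIANT_LOOKUP:
        out["surname"] = corrupt_field(out["surname"], "phonetic_swap", rng)
    if out["surname"] and _maybe(rng, t):
        out["surname"] = corrupt_field(out["surname"], "typo", rng)
    if out["surname"] and _maybe(rng, ms * 0.1):
        out["surname"] = MISSING
    if out["given_names"] and _maybe(rng, t):
        out["given_names"] = corrupt_field(out["given_names"], "typo", rng)
    if out["given_names"] and _maybe(rng, ms):
        out["given_names"] = MISSING
    if out["sex"] and _maybe(rng, ms):
        out["sex"] = MISSING
    bd = out["birth_date"]
    if bd and _maybe(rng, dtr):
        d = dt.date.fromisoformat(bd)
        if d.day <= 12 and d.day != d.month:
            out["birth_date"] = corrupt_field(bd, "date_transpose", rng)
    if out["birth_date"] and _maybe(rng, ms * 0.25):
        out["birth_date"] = MISSING
    if out["postal_code"] and _maybe(rng, t):
        out["postal_code"] = corrupt_field(out["postal_code"], "typo", rng)
    if out["postal_code"] and _maybe(rng, ms):
        out["postal_code"] = MISSING
    return out


def _person_cycle(n: int, rng):
    """Yield registry indices, reshuffling when exhausted (small registries)."""
    while True:
        for i in rng.permutation(n):
            yield int(i)


def _attrs_for(cfg, rng, surname: str, unlinkable: bool, event: dt.date) -> dict:
    if cfg.kind == "immigration":
        classes, wts = zip(*[(c, w) for c, w in _IMMIGRANT_CLASSES])
        cls = classes[int(rng.choice(len(classes), p=np.array(wts) / sum(wts)))]
        if surname.upper() in cfg.common_pool and rng.random() < 0.75:
            region = "Eastern Asia"
        else:
            region = _REGIONS_OTHER[int(rng.integers(0, len(_REGIONS_OTHER)))]
        return {"immigrant_class": cls, "region_of_birth": region}
    causes, wts = zip(*[(c, w) for c, w in _CAUSES])
    if unlinkable and rng.random() < 0.6:
        cause = "Perinatal"
    else:
        cause = causes[int(rng.choice(len(causes), p=np.array(wts) / sum(wts)))]
    return {"cause_of_death": cause}


def derive_source(
    config: SyntheticConfig, registry: list[RegistryRecord]
) -> tuple[list[SourceRecord], GroundTruthMap]:
    """Derive ``n_source`` source records plus their ground-truth map.

    Each record is either a corrupted copy of a registry person's
    identifiers plus an event date and stratification attributes, or (with
    probability ``unlinkable_frac``) an invention with no counterpart.
    Corruption applies each per-field operator independently at its rate
    scaled by the era multiplier of the record's event year; duplicate
    records of one person differ in event date.
    """
    config.validate()
    if not registry:
        raise ValueError("derive_source: registry must be nonempty")

    sel = substream(config.seed, "source.select")
    corr = substream(config.seed, "source.corrupt")
    inv = substream(config.seed, "source.invent")
    att = substream(config.seed, "source.attrs")
    ev_rng = substream(config.seed, "source.events")

    ey0, ey1 = config.effective_event_years
    persons = _person_cycle(len(registry), sel)
    sources: list[SourceRecord] = []
    truth = GroundTruthMap()

    pending: list[tuple[Optional[RegistryRecord], Optional[dt.date]]] = []
    while len(pending) < config.n_source:
        if sel.random() < config.unlinkable_frac:
            pending.append((None, None))
            continue
        person = registry[next(persons)]
        pending.append((person, None))
        if len(pending) < config.n_source and sel.random() < config.dup_frac:
            pending.append((person, "dup"))  # marker; event offset below

    for idx, (person, dup) in enumerate(pending):
        sid = f"S{idx + 1:07d}"
        if person is None:
            event = _random_date(ev_rng, ey0, ey1)
            surname = _surname(inv, config)
            attrs = _attrs_for(config, att, surname, True, event)
            if config.kind == "death" and attrs.get("cause_of_death") == "Perinatal":
                birth = event - dt.timedelta(days=int(inv.integers(0, 28)))
            else:
                birth = _random_date(inv, *config.birth_year_range)
            sources.append(
                SourceRecord(
                    source_id=sid,
                    surname=surname,
                    given_names=_given(inv),
                    sex="F" if inv.random() < 0.5 else "M",
                    birth_date=birth.isoformat(),
                    event_date=event.isoformat(),
                    postal_code=_postal(inv),
                    attrs={**attrs, "event_year": str(event.year)},
                )
            )
            truth[sid] = None
            continue

        if config.kind == "death":
            lc = dt.date.fromisoformat(person.last_contact)
            event = lc + dt.timedelta(days=int(ev_rng.integers(-10, 21)))
        else:
            event = _random_date(ev_rng, ey0, ey1)
            birth = dt.date.fromisoformat(person.birth_date)
            if event < birth:
                event = min(birth, dt.date(ey1, 12, 31))
        if dup == "dup":
            off = int(ev_rng.integers(30, 400)) if config.kind == "immigration" \
                else int(ev_rng.integers(1, 60))
            event = event + dt.timedelta(days=off)
        event = min(max(event, dt.date(ey0, 1, 1)), dt.date(ey1, 12, 31))
        if dup == "dup" and sources and truth.get(sources[-1].source_id) == person.key \
                and sources[-1].event_date == event.isoformat():
            event -= dt.timedelta(days=1)   # duplicates must differ in event date

        mult = config.era_multiplier(event.year)
        ident = _corrupt_identifiers(
            {
                "surname": person.surname,
                "given_names": person.given_names,
                "sex": person.sex,
                "birth_date": person.birth_date,
                "postal_code": person.postal_code,
            },
            mult, config, corr,
        )
        attrs = _attrs_for(config, att, person.surname, False, event)
        sources.append(
            SourceRecord(
                source_id=sid,
                surname=ident["surname"],
                given_names=ident["given_names"],
                sex=ident["sex"],
                birth_date=ident["birth_date"],
                event_date=event.isoformat(),
                postal_code=ident["postal_code"],
                attrs={**attrs, "event_year": str(event.year)},
            )
        )
        truth[sid] = person.key

    return sources, truth


# ---------------------------------------------------------------------------
# CSV writers (UTF-8, comma-delimited, header row; missing = empty string)
# ---------------------------------------------------------------------------

REGISTRY_COLUMNS = (
    "key", "surname", "given_names", "sex", "birth_date",
    "coverage_start", "last_contact", "postal_code",
)
SOURCE_BASE_COLUMNS = (
    "source_id", "surname", "given_names", "sex", "birth_date",
    "event_date", "postal_code",
)


def write_registry_csv(records: Iterable[RegistryRecord], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(REGISTRY_COLUMNS)
        for r in records:
            w.writerow([getattr(r, c) for c in REGISTRY_COLUMNS])


def write_source_csv(records: list[SourceRecord], path) -> None:
    attr_cols = sorted({k for r in records for k in r.attrs})
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(list(SOURCE_BASE_COLUMNS) + attr_cols)
        for r in records:
            w.writerow(
                [getattr(r, c) for c in SOURCE_BASE_COLUMNS]
                + [r.attrs.get(k, "") for k in attr_cols]
            )


def write_truth_csv(truth: GroundTruthMap, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["source_id", "registry_key"])
        for sid in sorted(truth):
            w.writerow([sid, truth[sid] or ""])
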