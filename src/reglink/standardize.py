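"""Identifier standardization: name cleaning, NYSIIS coding, city derivation.

Matching operates on standardized forms only: surnames and given names are
uppercased, stripped of diacritics and punctuation; surnames additionally get
a NYSIIS phonetic code so that spelling variants (BROWN/BRAUN, MACDONALD/
MCDONALD) fall into the same comparison block; postal codes are mapped to a
coarse city code used as geographic side-evidence when reviewing uncertain
pairs.

The NYSIIS implementation follows the original 1970 New York State
Identification and Intelligence System rule set (not the later "modified"
variant), with the code length uncapped by default; both choices are
configurable and recorded in the run log by the pipeline.
"""
from __future__ import annotations

import csv
import datetime as dt
import unicodedata
from typing import Iterable, Optional

from .model import MISSING, RegistryRecord, SourceRecord, StandardizedRecord

__all__ = [
    "clean_name",
    "nysiis",
    "PostalCityTable",
    "UNKNOWN_CITY",
    "parse_date_parts",
    "parse_date",
    "standardize_registry",
    "standardize_source",
]

UNKNOWN_CITY = "UNKNOWN"

_VOWELS = frozenset("AEIOU")


def clean_name(raw: str) -> str:
    """Uppercase, strip diacritics, drop everything outside A-Z.

    Total and idempotent: any text maps to a (possibly empty) A-Z string.

    >>> clean_name("O'Brien")
    'OBRIEN'
    >>> clean_name("Müller-Lopez")
    'MULLERLOPEZ'
    """
    decomposed = unicodedata.normalize("NFKD", raw.upper())
    return "".join(c for c in decomposed if "A" <= c <= "Z")


# Initial-string and terminal-string replacements, longest pattern first.
_NYSIIS_FIRST = (("MAC", "MCC"), ("KN", "NN"), ("K", "C"),
                 ("PH", "FF"), ("PF", "FF"), ("SCH", "SSS"))
_NYSIIS_LAST = (("EE", "Y"), ("IE", "Y"),
                ("DT", "D"), ("RT", "D"), ("RD", "D"), ("NT", "D"), ("ND", "D"))


def nysiis(name: str, truncate: Optional[int] = None) -> str:
    """NYSIIS phonetic code of an already-cleaned (A-Z) surname.

    The code head is the first letter after the initial-string replacement
    (so KNIGHT -> NN... -> NAGT), interior letters are transformed
    iteratively (vowels to A, Q to G, Z to S, M to N, KN to N, K to C,
    SCH to SSS, PH to FF, H next to a non-vowel and W after a vowel copy the
    previous letter) with doubled letters collapsed, and a terminal S / AY /
    A cleanup is applied.  ``truncate`` optionally caps the code length
    (some deployments cap at 6); default is uncapped.

    >>> nysiis("KNIGHT")
    'NAGT'
    >>> nysiis("BROWN") == nysiis("BRAUN")
    True
    """
    if name == "":
        return ""
    if not (name.isascii() and name.isalpha() and name.isupper()):
        raise ValueError(f"nysiis expects cleaned A-Z input, got {name!r}")

    s = list(name)
    for pat, rep in _NYSIIS_FIRST:
        if name.startswith(pat):
            s[: len(pat)] = rep
            break
    tail = "".join(s)
    for pat, rep in _NYSIIS_LAST:
        if tail.endswith(pat):
            s[-len(pat):] = rep
            break

    key = [s[0]]
    i = 1
    while i < len(s):
        c = s[i]
        nxt = s[i + 1] if i + 1 < len(s) else ""
        if c in _VOWELS:
            if c == "E" and nxt == "V":
                s[i: i + 2] = ["A", "F"]
            else:
                s[i] = "A"
        elif c == "Q":
            s[i] = "G"
        elif c == "Z":
            s[i] = "S"
        elif c == "M":
            s[i] = "N"
        elif c == "K":
            if nxt == "N":
                s[i: i + 2] = ["N"]
            else:
                s[i] = "C"
        elif c == "S" and "".join(s[i: i + 3]) == "SCH":
            s[i: i + 3] = ["S", "S", "S"]
        elif c == "P" and nxt == "H":
            s[i: i + 2] = ["F", "F"]
        elif c == "H" and (s[i - 1] not in _VOWELS or nxt not in _VOWELS):
            s[i] = s[i - 1]
        elif c == "W" and s[i - 1] in _VOWELS:
            s[i] = s[i - 1]
        if s[i] != key[-1]:
            key.append(s[i])
        i += 1

    if len(key) > 1 and key[-1] == "S":
        key.pop()
    if len(key) > 1 and key[-2:] == ["A", "Y"]:
        key[-2:] = ["Y"]
    if len(key) > 1 and key[-1] == "A":
        key.pop()
    code = "".join(key)
    return code[:truncate] if truncate else code


class PostalCityTable:
    """Longest-prefix map from postal codes to coarse city codes.

    Lookup is total: an empty/unmatched postal code yields ``UNKNOWN``,
    which downstream stages treat as "no geographic evidence", never as
    agreement.
    """

    def __init__(self, pairs: Iterable[tuple[str, str]]):
        self._table: dict[str, str] = {}
        for prefix, city in pairs:
            p = prefix.strip().upper()
            if p in self._table:
                raise ValueError(f"duplicate postal prefix {p!r}")
            self._table[p] = city.strip().upper()
        self._max_len = max((len(p) for p in self._table), default=0)

    @classmethod
    def from_csv(cls, path) -> "PostalCityTable":
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.reader(fh)
            header = next(reader, None)
            rows = [(r[0], r[1]) for r in reader if len(r) >= 2]
        return cls(rows)

    @property
    def prefixes(self) -> tuple[str, ...]:
        return tuple(self._table)

    def city_of(self, postal: str) -> str:
        p = (postal or "").strip().upper().replace(" ", "")
        for n in range(min(len(p), self._max_len), 0, -1):
            city = self._table.get(p[:n])
            if city is not None:
                return city
        return UNKNOWN_CITY


def city_of(postal: str, table: PostalCityTable) -> str:
    """Longest-prefix city lookup; UNKNOWN when unmatched or missing."""
    return table.city_of(postal)


def parse_date_parts(text: str) -> tuple[Optional[int], Optional[int], Optional[int]]:
    """Split an ISO-ish date into (year, month, day); parts may be missing.

    Accepts YYYY-MM-DD with empty components (e.g. "1950--" for a
    year-only date); anything unparseable is treated as missing.
    """
    if not text:
        return (None, None, None)
    parts = (text.split("-") + ["", "", ""])[:3]

    def _int(p, lo, hi):
        try:
            v = int(p)
        except ValueError:
            return None
        return v if lo <= v <= hi else None

    return (_int(parts[0], 1, 9999), _int(parts[1], 1, 12), _int(parts[2], 1, 31))


def parse_date(text: str) -> Optional[dt.date]:
    y, m, d = parse_date_parts(text)
    if None in (y, m, d):
        return None
    try:
        return dt.date(y, m, d)
    except ValueError:
        return None


def _given_clean(raw: str) -> tuple[str, ...]:
    parts = [clean_name(p) for p in (raw or "").replace("-", " ").split()]
    return tuple(p for p in parts if p)


def _standardize(
    rid: str,
    surname: str,
    given: str,
    sex: str,
    birth: str,
    postal: str,
    table: Optional[PostalCityTable],
    event: str = MISSING,
    last_contact: str = MISSING,
    attrs: Optional[dict] = None,
    nysiis_truncate: Optional[int] = None,
    code_given: bool = False,
) -> StandardizedRecord:
    sc = clean_name(surname or "")
    gc = _given_clean(given)
    sx = (sex or "").strip().upper()
    by, bm, bd = parse_date_parts(birth or "")
    return StandardizedRecord(
        rid=rid,
        surname_clean=sc,
        given_clean=gc,
        surname_nysiis=nysiis(sc, nysiis_truncate) if sc else "",
        given_initial=(gc[0][0] if gc else ""),
        birth_year=by,
        birth_month=bm,
        birth_day=bd,
        sex=sx if sx in ("F", "M") else "",
        city_code=table.city_of(postal or "") if table else UNKNOWN_CITY,
        postal_code=(postal or "").strip().upper(),
        event_date=parse_date(event or ""),
        last_contact=parse_date(last_contact or ""),
        attrs=dict(attrs or {}),
    )


def standardize_registry(
    records: Iterable[RegistryRecord],
    table: Optional[PostalCityTable] = None,
    nysiis_truncate: Optional[int] = None,
) -> list[StandardizedRecord]:
    return [
        _standardize(
            r.key, r.surname, r.given_names, r.sex, r.birth_date, r.postal_code,
            table, last_contact=r.last_contact, nysiis_truncate=nysiis_truncate,
        )
        for r in records
    ]


def standardize_source(
    records: Iterable[SourceRecord],
    table: Optional[PostalCityTable] = None,
    nysiis_truncate: Optional[int] = None,
) -> list[StandardizedRecord]:
    return [
        _standardize(
            r.source_id, r.surname, r.given_names, r.sex, r.birth_date,
            r.postal_code, table, event=r.event_date, attrs=r.attrs,
            nysiis_truncate=nysiis_truncate,
        )
        for r in records
    ]
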