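"""Resolution: rule-based review, uniqueness, deduplication, link keys.

The grey zone left by the probabilistic stage is adjudicated by a
deterministic reviewer that mimics what a clerical reviewer would check:
enough weight, geographic agreement between the two files' city codes, and
no close competitor.  Afterwards, duplicate source records claiming the same
registry person are resolved by the source kind's retention rule (death:
best linkage quality, then death date closest to the registry's last-contact
date; immigration: earliest landing date), and every linked registry person
receives an opaque surrogate link key.
"""
from __future__ import annotations

import datetime as dt
import hashlib
import logging
from dataclasses import dataclass
from typing import Iterable, Optional

from .model import (
    LINKED_DETERMINISTIC,
    LINKED_PROBABILISTIC,
    LINKED_REVIEW,
    UNLINKED,
    ConfigError,
    LinkDecision,
    StandardizedRecord,
)
from .probabilistic import ReviewItem

__all__ = [
    "ReviewRule",
    "auto_review",
    "enforce_one_to_one",
    "dedup_death",
    "dedup_immigration",
    "deduplicate",
    "assign_link_keys",
    "LinkKeyMap",
]

log = logging.getLogger(__name__)

_TIER = {LINKED_DETERMINISTIC: 3, LINKED_PROBABILISTIC: 2, LINKED_REVIEW: 1, UNLINKED: 0}
_UNKNOWN = "UNKNOWN"


@dataclass(frozen=True)
class ReviewRule:
    """Acceptance rule for grey-zone pairs.

    A pair is accepted iff its weight reaches ``min_weight``, the two files'
    city codes agree (unless ``require_city_agreement`` is off; UNKNOWN
    never counts as agreement), and the best candidate beats its runner-up
    by at least ``max_competitor_gap`` bits.
    """

    require_city_agreement: bool = True
    min_weight: float = 4.0
    max_competitor_gap: float = 1.0

    def accepts(self, item: ReviewItem) -> bool:
        if item.weight < self.min_weight:
            return False
        if self.require_city_agreement:
            if item.city_source == _UNKNOWN or item.city_registry == _UNKNOWN:
                return False
            if item.city_source != item.city_registry:
                return False
        return item.competitor_gap >= self.max_competitor_gap


def auto_review(queue: Iterable[ReviewItem], rule: ReviewRule) -> list[LinkDecision]:
    """Adjudicate every queued pair; rejected records become unlinked."""
    out = []
    for item in queue:
        if rule.accepts(item):
            out.append(
                LinkDecision(item.source_id, item.registry_key, LINKED_REVIEW,
                             item.pass_id, item.weight)
            )
        else:
            out.append(LinkDecision(item.source_id, None, UNLINKED, None, None))
    return out


def _claim_rank(d: LinkDecision, seq: int) -> tuple:
    # higher tier, then higher weight, then earlier pass, then stable order
    w = d.weight if d.weight is not None else float("inf")
    p = d.pass_id if d.pass_id is not None else 1 << 30
    return (-_TIER[d.status], -w, p, seq)


def enforce_one_to_one(decisions: list[LinkDecision]) -> list[LinkDecision]:
    """Keep the best claimant per registry key; losers revert to unlinked.

    Quality order: deterministic > probabilistic > review, then weight,
    then earlier pass, then stable input order.  Intended for source files
    declared unique-per-person; files with legitimate within-source
    duplicates are handled by deduplication instead.
    """
    by_key: dict[str, list[tuple[tuple, int]]] = {}
    for i, d in enumerate(decisions):
        if d.linked:
            by_key.setdefault(d.registry_key, []).append((_claim_rank(d, i), i))
    losers: set[int] = set()
    for claims in by_key.values():
        claims.sort()
        for _, i in claims[1:]:
            losers.add(i)
    out = []
    for i, d in enumerate(decisions):
        if i in losers:
            out.append(LinkDecision(d.source_id, None, UNLINKED, None, None))
        else:
            out.append(d)
    return out


def _death_rank(
    d: LinkDecision,
    seq: int,
    event: Optional[dt.date],
    last_contact: Optional[dt.date],
) -> tuple:
    w = d.weight if d.weight is not None else float("inf")
    if event is not None and last_contact is not None:
        closeness = abs((event - last_contact).days)
    else:
        closeness = 1 << 30
    event_ord = event.toordinal() if event is not None else 1 << 30
    return (-_TIER[d.status], -w, closeness, event_ord, seq)


def dedup_death(
    group: list[tuple[LinkDecision, int, Optional[dt.date]]],
    last_contact: Optional[dt.date],
) -> int:
    """Surviving claimant among death records linked to one registry person.

    ``group`` holds (decision, stable sequence, death date) triples.  Keeps
    the best linkage quality tier, then highest weight, then the death date
    closest to the registry last-contact date, then the earliest death
    date, then stable order.  Returns the surviving sequence number.
    """
    ranked = sorted(
        group, key=lambda t: _death_rank(t[0], t[1], t[2], last_contact)
    )
    return ranked[0][1]


def dedup_immigration(group: list[tuple[LinkDecision, int, Optional[dt.date]]]) -> int:
    """Earliest landing date wins; ties by stable order."""
    ranked = sorted(
        group,
        key=lambda t: (t[2].toordinal() if t[2] is not None else 1 << 30, t[1]),
    )
    return ranked[0][1]


def deduplicate(
    decisions: list[LinkDecision],
    source_by_id: dict[str, StandardizedRecord],
    kind: str,
    registry_by_id: Optional[dict[str, StandardizedRecord]] = None,
) -> tuple[set[str], list[dict]]:
    """Pick one surviving source record per linked registry person.

    Returns (surviving source ids among linked records, audit rows for the
    discarded duplicates).  Unlinked records are untouched.
    """
    if kind not in ("immigration", "death"):
        raise ConfigError(f"dedup: unknown source kind {kind!r}")
    groups: dict[str, list[tuple[LinkDecision, int, Optional[dt.date]]]] = {}
    for i, d in enumerate(decisions):
        if d.linked:
            ev = source_by_id[d.source_id].event_date
            groups.setdefault(d.registry_key, []).append((d, i, ev))
    survivors: set[str] = set()
    audit: list[dict] = []
    for key, group in groups.items():
        if kind == "death":
            lc = None
            if registry_by_id is not None and key in registry_by_id:
                lc = registry_by_id[key].last_contact
            win = dedup_death(group, lc)
        else:
            win = dedup_immigration(group)
        win_sid = decisions[win].source_id
        survivors.add(win_sid)
        for d, i, ev in group:
            if i != win:
                audit.append(
                    {
                        "source_id": d.source_id,
                        "registry_key": key,
                        "status": d.status,
                        "weight": d.weight,
                        "event_date": ev.isoformat() if ev else "",
                        "kept_source_id": win_sid,
                        "reason": f"duplicate of {win_sid} under {kind} retention rule",
                    }
                )
    return survivors, audit


@dataclass
class LinkKeyMap:
    """Injective registry_key -> opaque link key map, stable within a run."""

    entries: dict[str, str]

    def __getitem__(self, registry_key: str) -> str:
        return self.entries[registry_key]

    def __len__(self) -> int:
        return len(self.entries)


def assign_link_keys(
    decisions: list[LinkDecision],
    salt: Optional[str] = None,
) -> tuple[LinkKeyMap, dict[str, str]]:
    """Attach an opaque surrogate key to every linked registry person.

    Without a salt, keys are sequential over the sorted registry keys
    (per-run surrogates); with a user-supplied salt they are salted hashes,
    stable across runs for the same salt.  Injectivity is asserted; a hash
    collision regenerates with a perturbed salt (logged).
    """
    keys = sorted({d.registry_key for d in decisions if d.linked})
    entries: dict[str, str] = {}
    if salt is None:
        for i, k in enumerate(keys, start=1):
            entries[k] = f"LK{i:08d}"
    else:
        attempt = salt
        while True:
            entries = {
                k: hashlib.blake2s(f"{attempt}|{k}".encode(), digest_size=8).hexdigest()
                for k in keys
            }
            if len(set(entries.values())) == len(entries):
                break
            log.warning("link-key hash collision; regenerating with perturbed salt")
            attempt = attempt + "#"
    assert len(set(entries.values())) == len(entries), "link keys must be injective"
    by_source = {
        d.source_id: entries[d.registry_key] for d in decisions if d.linked
    }
    return LinkKeyMap(entries), by_source
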