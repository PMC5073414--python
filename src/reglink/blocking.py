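"""Blocking: partition both files into comparable subsets, enumerate pairs.

Comparing all source x registry pairs is quadratic and infeasible at
registry scale, so each pass first partitions both files by a small tuple of
standardized key fields (sex, NYSIIS surname code, birth year, ...) and only
within-block pairs become candidates.  With ``missing_policy="own_block"``
the blocks are mutually exclusive and exhaustive (the partition property the
candidate counts rely on); ``broadcast`` instead compares records missing a
key field against every value of that field, trading the partition property
for a chance to link records with, e.g., missing sex.
"""
from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Iterator

from .model import BlockScheme, StandardizedRecord, field_value

__all__ = ["BlockScheme", "BlockIndex", "build_blocks", "candidate_pairs", "pairs_by_source"]


@dataclass
class BlockIndex:
    """Within-block membership of source and registry records.

    ``blocks`` maps a key tuple to (source ids, registry ids); records that
    fall under the broadcast policy are kept aside with their partial keys
    (``None`` marking the wildcard slots).
    """

    scheme: BlockScheme
    blocks: dict[tuple, tuple[list[str], list[str]]] = field(default_factory=dict)
    bc_source: list[tuple[str, tuple]] = field(default_factory=list)
    bc_registry: list[tuple[str, tuple]] = field(default_factory=list)

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    def candidate_count(self) -> int:
        return sum(1 for _ in candidate_pairs(self))


def _key_of(rec: StandardizedRecord, scheme: BlockScheme) -> tuple:
    return tuple(field_value(rec, f) for f in scheme.key_fields)


def build_blocks(
    source: Iterable[StandardizedRecord],
    registry: Iterable[StandardizedRecord],
    scheme: BlockScheme,
) -> BlockIndex:
    """Group both files by the scheme's key tuple.

    With ``own_block`` a missing key field is just another key value
    (``None``), so every record lands in exactly one block.  With
    ``broadcast`` records with any missing key field are set aside and
    matched against all compatible blocks when pairs are enumerated.
    """
    index = BlockIndex(scheme=scheme)
    grouped: dict[tuple, tuple[list, list]] = defaultdict(lambda: ([], []))
    broadcast = scheme.missing_policy == "broadcast"
    for pos, recs in ((0, source), (1, registry)):
        for rec in recs:
            key = _key_of(rec, scheme)
            if broadcast and any(v is None for v in key):
                (index.bc_source if pos == 0 else index.bc_registry).append((rec.rid, key))
            else:
                grouped[key][pos].append(rec.rid)
    index.blocks = dict(grouped)
    return index


def _compatible(partial: tuple, key: tuple) -> bool:
    return all(p is None or p == k for p, k in zip(partial, key))


def candidate_pairs(index: BlockIndex) -> Iterator[tuple[str, str]]:
    """Yield within-block (source_id, registry_id) pairs, each exactly once."""
    for sids, rids in index.blocks.values():
        for s in sids:
            for r in rids:
                yield (s, r)
    # broadcast source records against every compatible block
    for s, partial in index.bc_source:
        for key, (_, rids) in index.blocks.items():
            if _compatible(partial, key):
                for r in rids:
                    yield (s, r)
    # regular source blocks against broadcast registry records
    for r, partial in index.bc_registry:
        for key, (sids, _) in index.blocks.items():
            if _compatible(partial, key):
                for s in sids:
                    yield (s, r)
    # broadcast vs broadcast: compatible wherever both defined slots agree
    for s, pk in index.bc_source:
        for r, rk in index.bc_registry:
            if all(a is None or b is None or a == b for a, b in zip(pk, rk)):
                yield (s, r)


def pairs_by_source(index: BlockIndex) -> dict[str, list[str]]:
    """Candidate registry ids grouped by source id."""
    out: dict[str, list[str]] = defaultdict(list)
    for s, r in candidate_pairs(index):
        out[s].append(r)
    return dict(out)
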