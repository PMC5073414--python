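"""Deterministic (exact-match) linkage passes.

Each pass links a source record iff exactly one registry record in its block
agrees on every match field under that field's comparator; a missing value
on either side counts as disagreement, and an ambiguous record (two or more
agreeing candidates — the common-surname failure mode) is deliberately NOT
linked and flows on to later, more lenient passes.  Records linked in a pass
leave the cascade.
"""
from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Optional

from . import probabilistic
from .blocking import build_blocks, pairs_by_source
from .model import (
    AGREE,
    ConfigError,
    LINKED_DETERMINISTIC,
    LinkDecision,
    PassSpec,
    StandardizedRecord,
    compare_field,
    field_value,
    has_unhashable,
    hash_key,
)

__all__ = ["run_deterministic_pass", "run_pass_sequence", "PassLog"]


def _agrees(src, reg, spec: PassSpec) -> bool:
    for fld, cname in spec.match_fields:
        if compare_field(src, reg, fld, cname, spec.window_days) != AGREE:
            return False
    return True


def run_deterministic_pass(
    source: list[StandardizedRecord],
    registry: list[StandardizedRecord],
    spec: PassSpec,
) -> tuple[list[LinkDecision], list[StandardizedRecord]]:
    """One exact-match pass over the still-unlinked source records.

    Returns the decisions made in this pass and the residual source records
    that flow to the next pass.  Equality-style comparators are matched
    through a hash on (block key, canonical match values), which is exact
    and linear; passes containing a windowed comparator fall back to a
    within-block scan.
    """
    if spec.mode != "deterministic":
        raise ConfigError(f"pass {spec.pass_id}: run_deterministic_pass needs mode=deterministic")

    decisions: list[LinkDecision] = []
    linked_ids: set[str] = set()

    if not has_unhashable(spec.match_fields):
        # hash path: block key + canonical agreement token
        table: dict[tuple, list[str]] = defaultdict(list)
        for reg in registry:
            key = hash_key(reg, spec.match_fields, spec.window_days)
            if key is None:
                continue
            block = tuple(field_value(reg, f) for f in spec.block_scheme.key_fields)
            table[block + key].append(reg.rid)
        for src in source:
            key = hash_key(src, spec.match_fields, spec.window_days)
            if key is None:
                continue
            block = tuple(field_value(src, f) for f in spec.block_scheme.key_fields)
            cands = table.get(block + key, ())
            if len(cands) == 1:
                decisions.append(
                    LinkDecision(src.rid, cands[0], LINKED_DETERMINISTIC, spec.pass_id)
                )
                linked_ids.add(src.rid)
    else:
        reg_by_id = {r.rid: r for r in registry}
        src_by_id = {s.rid: s for s in source}
        index = build_blocks(source, registry, spec.block_scheme)
        for sid, rids in pairs_by_source(index).items():
            src = src_by_id[sid]
            matches = [rid for rid in rids if _agrees(src, reg_by_id[rid], spec)]
            if len(matches) == 1:
                decisions.append(
                    LinkDecision(sid, matches[0], LINKED_DETERMINISTIC, spec.pass_id)
                )
                linked_ids.add(sid)

    residual = [s for s in source if s.rid not in linked_ids]
    return decisions, residual


class PassLog:
    """Per-pass counts sufficient to redraw the linkage flow diagram."""

    def __init__(self):
        self.rows: list[dict] = []

    def add(self, pass_id: int, mode: str, n_in: int, n_linked: int,
            n_review: int = 0, n_candidates: Optional[int] = None):
        self.rows.append(
            {
                "pass_id": pass_id,
                "mode": mode,
                "records_in": n_in,
                "linked": n_linked,
                "to_review": n_review,
                "candidates": n_candidates,
            }
        )

    def as_dicts(self) -> list[dict]:
        return list(self.rows)


def run_pass_sequence(
    source: list[StandardizedRecord],
    registry: list[StandardizedRecord],
    specs: Iterable[PassSpec],
    log: Optional[PassLog] = None,
) -> tuple[list[LinkDecision], list["probabilistic.ReviewItem"]]:
    """Execute the ordered deterministic/probabilistic cascade.

    Records linked in a pass leave the pipeline; records emitted to the
    review queue by a probabilistic pass await adjudication and do not flow
    further; records surviving every pass are unlinked.  The returned
    decisions cover every input source record exactly once (records pending
    review carry status ``unlinked`` until resolution adjudicates them).
    """
    specs = list(specs)
    if not specs:
        raise ConfigError("pass sequence must be nonempty")
    ids = [s.pass_id for s in specs]
    if ids != sorted(ids) or len(set(ids)) != len(ids):
        raise ConfigError("pass_ids must be strictly increasing")

    decisions: list[LinkDecision] = []
    review: list[probabilistic.ReviewItem] = []
    residual = list(source)
    for spec in specs:
        n_in = len(residual)
        if spec.mode == "deterministic":
            made, residual = run_deterministic_pass(residual, registry, spec)
            decisions.extend(made)
            if log is not None:
                log.add(spec.pass_id, spec.mode, n_in, len(made))
        else:
            made, items, residual, n_cand = probabilistic.run_probabilistic_pass(
                residual, registry, spec
            )
            decisions.extend(made)
            review.extend(items)
            if log is not None:
                log.add(spec.pass_id, spec.mode, n_in, len(made), len(items), n_cand)

    decided = {d.source_id for d in decisions} | {it.source_id for it in review}
    for rec in source:
        if rec.rid not in decided:
            decisions.append(LinkDecision(rec.rid, None, "unlinked", None))
    # review items get their final status in resolution; placeholder decisions
    # are NOT emitted for them here to avoid double-decisions.
    return decisions, review
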