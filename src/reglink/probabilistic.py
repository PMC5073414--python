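"""Probabilistic linkage: Fellegi-Sunter log-odds scoring and EM estimation.

Each candidate pair gets a comparison vector (agree / disagree / missing per
field) and a total weight in bits: an agreement on field f contributes
log2(m_f/u_f), a disagreement log2((1-m_f)/(1-u_f)), a missing value 0 (no
evidence — death registrations legally require only sex and dates, so
penalizing absence would manufacture the very bias the evaluation stage is
meant to measure).  Weights at or above t_upper are definite matches, the
[t_lower, t_upper) band is the grey zone sent to review, anything lower is a
non-match.  When m/u are unknown they can be fitted by the classical
two-class EM under conditional independence.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .blocking import build_blocks, pairs_by_source
from .model import (
    AGREE,
    DISAGREE,
    MISSING_CMP,
    ConfigError,
    FieldModel,
    LINKED_PROBABILISTIC,
    LinkDecision,
    PassSpec,
    StandardizedRecord,
    Thresholds,
    compare_field,
)

__all__ = [
    "FieldModel",
    "Thresholds",
    "CandidatePair",
    "ReviewItem",
    "field_weight",
    "score_pair",
    "classify",
    "assign_matches",
    "run_probabilistic_pass",
    "em_estimate",
    "simulate_comparison_vectors",
    "EstimationError",
]

DEFINITE = "definite"
POSSIBLE = "possible"
NONMATCH = "nonmatch"


class EstimationError(RuntimeError):
    """EM could not fit the two-class model (degenerate input)."""


@dataclass
class CandidatePair:
    """A scored (source, registry) pair."""

    source_id: str
    registry_key: str
    vector: dict[str, str]
    weight: float


@dataclass
class ReviewItem:
    """A grey-zone pair queued for (rule-based) review."""

    source_id: str
    registry_key: str
    weight: float
    competitor_gap: float           # best minus runner-up weight (inf if none)
    vector: dict[str, str]
    pass_id: int
    city_source: str = "UNKNOWN"
    city_registry: str = "UNKNOWN"


def field_weight(model: FieldModel, outcome: str) -> float:
    """Log2-odds contribution of one field's comparison outcome (bits)."""
    model.validate()
    if outcome == AGREE:
        return math.log2(model.m / model.u)
    if outcome == DISAGREE:
        return math.log2((1.0 - model.m) / (1.0 - model.u))
    if outcome == MISSING_CMP:
        return 0.0
    raise ValueError(f"unknown comparison outcome {outcome!r}")


def score_pair(
    src: StandardizedRecord,
    reg: StandardizedRecord,
    spec: PassSpec,
) -> CandidatePair:
    """Compare the pass's fields and sum their weights."""
    vector: dict[str, str] = {}
    weight = 0.0
    for fld, cname in spec.match_fields:
        outcome = compare_field(src, reg, fld, cname, spec.window_days)
        vector[fld] = outcome
        weight += field_weight(spec.model_for(fld), outcome)
    return CandidatePair(src.rid, reg.rid, vector, weight)


def classify(pair_or_weight, th: Thresholds) -> str:
    """definite (w >= t_upper), possible (t_lower <= w < t_upper), nonmatch."""
    w = pair_or_weight.weight if isinstance(pair_or_weight, CandidatePair) else float(pair_or_weight)
    if w >= th.t_upper:
        return DEFINITE
    if w >= th.t_lower:
        return POSSIBLE
    return NONMATCH


def assign_matches(
    scored: dict[str, list[CandidatePair]],
    th: Thresholds,
    pass_id: int,
    margin: float = 1.0,
) -> tuple[list[LinkDecision], list[ReviewItem], set[str]]:
    """Per-source assignment of the best-scoring candidate.

    The highest-weight candidate is linked outright when it is definite and
    beats the runner-up by at least ``margin`` bits; a possible match, or a
    definite one inside the margin, goes to the review queue; everything
    else is left for later passes.  Ties are broken by registry key for
    determinism.  One-to-one enforcement across source records is deferred
    to resolution.
    """
    decisions: list[LinkDecision] = []
    review: list[ReviewItem] = []
    leftover: set[str] = set()
    for sid, pairs in scored.items():
        if not pairs:
            leftover.add(sid)
            continue
        ranked = sorted(pairs, key=lambda p: (-p.weight, p.registry_key))
        best = ranked[0]
        gap = best.weight - ranked[1].weight if len(ranked) > 1 else math.inf
        cls = classify(best, th)
        if cls == DEFINITE and gap >= margin:
            decisions.append(
                LinkDecision(sid, best.registry_key, LINKED_PROBABILISTIC, pass_id, best.weight)
            )
        elif cls == POSSIBLE or cls == DEFINITE:
            review.append(
                ReviewItem(sid, best.registry_key, best.weight, gap, best.vector, pass_id)
            )
        else:
            leftover.add(sid)
    return decisions, review, leftover


def run_probabilistic_pass(
    source: list[StandardizedRecord],
    registry: list[StandardizedRecord],
    spec: PassSpec,
) -> tuple[list[LinkDecision], list[ReviewItem], list[StandardizedRecord], int]:
    """Score within-block candidates and assign matches for one pass.

    Returns (decisions, review items, residual records, candidate count).
    """
    if spec.mode != "probabilistic":
        raise ConfigError(f"pass {spec.pass_id}: run_probabilistic_pass needs mode=probabilistic")
    reg_by_id = {r.rid: r for r in registry}
    src_by_id = {s.rid: s for s in source}
    index = build_blocks(source, registry, spec.block_scheme)
    grouped = pairs_by_source(index)
    n_candidates = sum(len(v) for v in grouped.values())
    scored = {
        sid: [score_pair(src_by_id[sid], reg_by_id[rid], spec) for rid in rids]
        for sid, rids in grouped.items()
    }
    for sid in src_by_id:
        scored.setdefault(sid, [])
    decisions, review, _ = assign_matches(scored, spec.thresholds, spec.pass_id, spec.margin)
    for item in review:
        src = src_by_id[item.source_id]
        reg = reg_by_id[item.registry_key]
        item.city_source = src.city_code
        item.city_registry = reg.city_code
    settled = {d.source_id for d in decisions} | {it.source_id for it in review}
    residual = [s for s in source if s.rid not in settled]
    return decisions, review, residual, n_candidates


# ---------------------------------------------------------------------------
# EM estimation of m/u probabilities
# ---------------------------------------------------------------------------

def em_estimate(
    vectors: np.ndarray,
    init_m: Sequence[float],
    init_u: Sequence[float],
    init_p: float = 0.1,
    tol: float = 1e-6,
    max_iter: int = 1000,
    fields: Optional[Sequence[str]] = None,
) -> tuple[list[FieldModel], float, int]:
    """Two-class EM under conditional independence on comparison vectors.

    ``vectors`` is an (n_pairs, n_fields) array coded 1=agree, 0=disagree,
    -1=missing (missing contributes nothing to either class's likelihood).
    Iterates until the largest parameter change is below ``tol`` or
    ``max_iter`` is hit; the match class is relabelled, if necessary, so
    that mean(m) > mean(u).  Returns (fitted field models, match
    proportion, iterations used).
    """
    V = np.asarray(vectors)
    if V.ndim != 2 or V.shape[1] < 2:
        raise ConfigError("em_estimate needs >= 2 comparison fields")
    n, k = V.shape
    if n == 0:
        raise EstimationError("no comparison vectors")
    if np.all(V == V[0]):
        raise EstimationError(
            "all comparison vectors are identical; the two-class mixture is unidentifiable"
        )
    A = (V == 1).astype(float)
    D = (V == 0).astype(float)

    m = np.clip(np.asarray(init_m, dtype=float), 1e-4, 1 - 1e-4)
    u = np.clip(np.asarray(init_u, dtype=float), 1e-4, 1 - 1e-4)
    if m.shape != (k,) or u.shape != (k,):
        raise ConfigError("init_m/init_u length must equal the number of fields")
    p = float(np.clip(init_p, 1e-4, 1 - 1e-4))

    eps = 1e-12
    for it in range(1, max_iter + 1):
        log_match = A @ np.log(m) + D @ np.log1p(-m) + math.log(p)
        log_non = A @ np.log(u) + D @ np.log1p(-u) + math.log(1.0 - p)
        hi = np.maximum(log_match, log_non)
        g = np.exp(log_match - hi) / (np.exp(log_match - hi) + np.exp(log_non - hi))

        denom_m = g @ (A + D) + eps
        denom_u = (1.0 - g) @ (A + D) + eps
        new_m = np.clip((g @ A) / denom_m, 1e-6, 1 - 1e-6)
        new_u = np.clip(((1.0 - g) @ A) / denom_u, 1e-6, 1 - 1e-6)
        new_p = float(np.clip(g.mean(), 1e-6, 1 - 1e-6))

        delta = max(
            float(np.max(np.abs(new_m - m))),
            float(np.max(np.abs(new_u - u))),
            abs(new_p - p),
        )
        m, u, p = new_m, new_u, new_p
        if delta < tol:
            break

    if m.mean() < u.mean():        # label switching: match class agrees more
        m, u, p = u, m, 1.0 - p

    names = list(fields) if fields is not None else [f"f{i}" for i in range(k)]
    models = [FieldModel(names[i], float(m[i]), float(u[i])) for i in range(k)]
    return models, p, it


def simulate_comparison_vectors(
    m: Sequence[float],
    u: Sequence[float],
    match_prop: float,
    n: int,
    rng: np.random.Generator,
    missing_rate: float = 0.0,
) -> np.ndarray:
    """Draw comparison vectors from the two-class independence model."""
    m = np.asarray(m, dtype=float)
    u = np.asarray(u, dtype=float)
    k = m.shape[0]
    is_match = rng.random(n) < match_prop
    probs = np.where(is_match[:, None], m[None, :], u[None, :])
    V = (rng.random((n, k)) < probs).astype(np.int8)
    if missing_rate > 0:
        V[rng.random((n, k)) < missing_rate] = -1
    return V
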