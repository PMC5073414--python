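"""Evaluation: linkage rates, method mix, standardized differences, truth metrics.

Linked and unlinked records are contrasted stratum by stratum: the linkage
rate of stratum s is 100 * n_linked / (n_linked + n_unlinked), and the
composition difference between the linked and unlinked files is measured by
the two-proportion standardized difference

    d = |p1 - p2| / sqrt((p1 (1 - p1) + p2 (1 - p2)) / 2)

with Cohen's conventional reading of 0.2 / 0.5 / 0.8 as small / moderate /
large.  No p-values are computed: at registry scale every difference is
"significant", so only effect sizes are informative.  On synthetic data with
a ground-truth map, precision/recall/F1 against the truth are also computed.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping, Optional

import pandas as pd

from .model import (
    LINKED_DETERMINISTIC,
    LINKED_PROBABILISTIC,
    LINKED_REVIEW,
    ConfigError,
    LinkDecision,
)

__all__ = [
    "round_half_up",
    "linkage_rate",
    "standardized_difference",
    "standardized_difference_means",
    "build_stratum_table",
    "method_mix",
    "MethodMix",
    "rates_by_period",
    "truth_metrics",
    "TruthMetrics",
]


def round_half_up(x: float, ndigits: int) -> float:
    """Decimal half-up rounding (the tables' presentation convention)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def linkage_rate(n_linked: int, n_unlinked: int) -> float:
    """Percentage of records matched to the registry; NaN on an empty stratum."""
    total = n_linked + n_unlinked
    if total <= 0:
        return math.nan
    return 100.0 * n_linked / total


def standardized_difference(p_linked: float, p_unlinked: float) -> float:
    """Pooled two-proportion standardized difference (dimensionless).

    Defined as 0 when both proportions are 0 or both are 1 (no variance,
    no difference).
    """
    for name, p in (("p_linked", p_linked), ("p_unlinked", p_unlinked)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must lie in [0,1], got {p}")
    var = (p_linked * (1 - p_linked) + p_unlinked * (1 - p_unlinked)) / 2.0
    if var == 0.0:
        return 0.0
    return abs(p_linked - p_unlinked) / math.sqrt(var)


def standardized_difference_means(
    mean1: float, sd1: float, mean2: float, sd2: float
) -> float:
    """Continuous-variable overload with pooled (averaged) variances."""
    var = (sd1 ** 2 + sd2 ** 2) / 2.0
    if var == 0.0:
        return 0.0
    return abs(mean1 - mean2) / math.sqrt(var)


def build_stratum_table(
    df: pd.DataFrame,
    variable: str,
    linked_col: str = "linked",
) -> pd.DataFrame:
    """One row per stratum of ``variable`` plus an Overall row.

    ``df`` carries one row per source record with a boolean ``linked``
    column; a missing attribute is its own stratum, and the within-file
    percentages use the full file as the base (so Missing rows count).
    """
    if variable not in df.columns:
        raise ConfigError(f"build_stratum_table: unknown variable {variable!r}")
    work = df[[variable, linked_col]].copy()
    work[variable] = work[variable].fillna("Missing").replace("", "Missing")
    n_linked_total = int(work[linked_col].sum())
    n_unlinked_total = int((~work[linked_col]).sum())

    rows = []
    for stratum, grp in work.groupby(variable, sort=True):
        nl = int(grp[linked_col].sum())
        nu = len(grp) - nl
        p1 = nl / n_linked_total if n_linked_total else 0.0
        p2 = nu / n_unlinked_total if n_unlinked_total else 0.0
        rows.append(
            {
                "variable": variable,
                "stratum": stratum,
                "n_linked": nl,
                "pct_linked": round_half_up(100 * p1, 1),
                "n_unlinked": nu,
                "pct_unlinked": round_half_up(100 * p2, 1),
                "std_diff": round_half_up(standardized_difference(p1, p2), 2),
                "linkage_rate": round_half_up(linkage_rate(nl, nu), 1)
                if nl + nu else math.nan,
            }
        )
    overall = {
        "variable": variable,
        "stratum": "Overall",
        "n_linked": n_linked_total,
        "pct_linked": 100.0,
        "n_unlinked": n_unlinked_total,
        "pct_unlinked": 100.0,
        "std_diff": math.nan,
        "linkage_rate": round_half_up(
            linkage_rate(n_linked_total, n_unlinked_total), 1
        ),
    }
    return pd.DataFrame([overall] + rows)


@dataclass(frozen=True)
class MethodMix:
    """Share of records linked deterministically / probabilistically / unlinked."""

    pct_deterministic: float
    pct_probabilistic: float        # includes review-accepted links
    pct_unlinked: float

    def as_dict(self) -> dict:
        return {
            "pct_deterministic": self.pct_deterministic,
            "pct_probabilistic": self.pct_probabilistic,
            "pct_unlinked": self.pct_unlinked,
        }


def method_mix(decisions: Iterable[LinkDecision]) -> MethodMix:
    counts = {"det": 0, "prob": 0, "unl": 0}
    n = 0
    for d in decisions:
        n += 1
        if d.status == LINKED_DETERMINISTIC:
            counts["det"] += 1
        elif d.status in (LINKED_PROBABILISTIC, LINKED_REVIEW):
            counts["prob"] += 1
        else:
            counts["unl"] += 1
    if n == 0:
        raise ConfigError("method_mix: no decisions")
    return MethodMix(
        pct_deterministic=100.0 * counts["det"] / n,
        pct_probabilistic=100.0 * counts["prob"] / n,
        pct_unlinked=100.0 * counts["unl"] / n,
    )


def rates_by_period(
    df: pd.DataFrame,
    period_col: str = "event_year",
    band_width: int = 5,
    status_col: str = "status",
) -> pd.DataFrame:
    """Linkage rate and method mix per period band (the era series).

    Bands are [k*w, (k+1)*w) on the period value; empty bands are omitted.
    The three percentage components sum to 100 within each band.
    """
    work = df[[period_col, status_col]].dropna(subset=[period_col]).copy()
    work["band"] = (work[period_col].astype(int) // band_width) * band_width
    rows = []
    for band, grp in work.groupby("band", sort=True):
        n = len(grp)
        n_det = int((grp[status_col] == LINKED_DETERMINISTIC).sum())
        n_prob = int(grp[status_col].isin([LINKED_PROBABILISTIC, LINKED_REVIEW]).sum())
        n_unl = n - n_det - n_prob
        rows.append(
            {
                "band": int(band),
                "n": n,
                "linkage_rate": 100.0 * (n_det + n_prob) / n,
                "pct_deterministic": 100.0 * n_det / n,
                "pct_probabilistic": 100.0 * n_prob / n,
                "pct_unlinked": 100.0 * n_unl / n,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class TruthMetrics:
    precision: float
    recall: float
    f1: float
    n_links: int
    n_correct: int
    n_false_links: int
    n_missed: int

    def as_dict(self) -> dict:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "n_links": self.n_links,
            "n_correct": self.n_correct,
            "n_false_links": self.n_false_links,
            "n_missed": self.n_missed,
        }


def truth_metrics(
    decisions: Iterable[LinkDecision],
    truth: Mapping[str, Optional[str]],
) -> TruthMetrics:
    """Precision/recall/F1 of the decisions against a ground-truth map.

    A link to the wrong registry person counts against both precision and
    recall.  With no links at all, precision is reported as 1.0 by
    convention (with a warning) and recall as 0.
    """
    decisions = list(decisions)
    missing = [d.source_id for d in decisions if d.source_id not in truth]
    if missing:
        raise ValueError(f"truth map is missing {len(missing)} source ids (e.g. {missing[0]!r})")

    n_links = n_correct = 0
    linked_ids = set()
    for d in decisions:
        if d.linked:
            n_links += 1
            linked_ids.add(d.source_id)
            if truth[d.source_id] == d.registry_key:
                n_correct += 1
    n_linkable = sum(
        1 for d in decisions if truth[d.source_id] is not None
    )
    n_false = n_links - n_correct
    n_missed = n_linkable - n_correct
    if n_links == 0:
        warnings.warn("no links made; precision reported as 1.0 by convention")
        precision = 1.0
    else:
        precision = n_correct / n_links
    recall = n_correct / n_linkable if n_linkable else 1.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if (precision + recall) > 0
        else 0.0
    )
    return TruthMetrics(precision, recall, f1, n_links, n_correct, n_false, n_missed)
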