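"""Benchmark tables: published stratum counts for derived-statistic checks.

Ships the stratum-level linked/unlinked counts reported by a published
province-wide linkage of an immigration permanent-resident file and a
vital-statistics death registry to a population registry, together with the
percentages, standardized differences and linkage rates printed alongside
them.  The real person-level data are confidential; the printed counts,
however, make every derived statistic recomputable, which turns the table
into an exact oracle for the evaluation module: feeding the counts through
``linkage_rate`` and ``standardized_difference`` must reproduce the printed
columns at their printed precision.
"""
from __future__ import annotations

from importlib import resources
from typing import Optional

import pandas as pd

from .evaluation import linkage_rate, round_half_up, standardized_difference

__all__ = ["load_benchmark_table", "recompute_benchmark", "benchmark_mismatches"]

_KINDS = ("immigration", "death")


def load_benchmark_table(kind: str) -> pd.DataFrame:
    """The shipped benchmark table for ``kind`` (printed values as strings)."""
    if kind not in _KINDS:
        raise ValueError(f"unknown benchmark kind {kind!r}")
    path = resources.files("reglink.data").joinpath(f"benchmark_{kind}.csv")
    with resources.as_file(path) as p:
        return pd.read_csv(p, dtype=str).fillna("")


def _decimals(printed: str) -> int:
    return len(printed.split(".")[1]) if "." in printed else 0


def recompute_benchmark(table: pd.DataFrame) -> pd.DataFrame:
    """Recompute rates, percentages and standardized differences from counts.

    Totals are taken from the Overall row; each derived column is rounded
    half-up to the precision its printed counterpart uses.
    """
    overall = table[table["stratum"] == "Overall"].iloc[0]
    total_linked = int(overall["n_linked"])
    total_unlinked = int(overall["n_unlinked"])

    rows = []
    for _, r in table.iterrows():
        nl, nu = int(r["n_linked"]), int(r["n_unlinked"])
        rate = linkage_rate(nl, nu)
        out = dict(r)
        out["linkage_rate_calc"] = round_half_up(rate, _decimals(r["linkage_rate"])) \
            if r["linkage_rate"] != "" else None
        if r["stratum"] == "Overall":
            out["pct_linked_calc"] = out["pct_unlinked_calc"] = out["std_diff_calc"] = None
        else:
            p1 = nl / total_linked
            p2 = nu / total_unlinked
            out["pct_linked_calc"] = round_half_up(100 * p1, _decimals(r["pct_linked"]))
            out["pct_unlinked_calc"] = round_half_up(100 * p2, _decimals(r["pct_unlinked"]))
            out["std_diff_calc"] = (
                round_half_up(standardized_difference(p1, p2), _decimals(r["std_diff"]))
                if r["std_diff"] != "" else None
            )
        rows.append(out)
    return pd.DataFrame(rows)


def benchmark_mismatches(table: Optional[pd.DataFrame] = None, kind: str = "immigration") -> list[dict]:
    """Cells whose recomputed value differs from the printed one.

    Returns one dict per mismatching cell (section, stratum, column,
    printed, recomputed).  An empty list means the printed table is fully
    internally consistent under the pooled two-proportion formula and
    half-up rounding.
    """
    if table is None:
        table = load_benchmark_table(kind)
    recomputed = recompute_benchmark(table)
    out = []
    pairs = (
        ("linkage_rate", "linkage_rate_calc"),
        ("pct_linked", "pct_linked_calc"),
        ("pct_unlinked", "pct_unlinked_calc"),
        ("std_diff", "std_diff_calc"),
    )
    for _, r in recomputed.iterrows():
        for printed_col, calc_col in pairs:
            printed, calc = r[printed_col], r[calc_col]
            if printed == "" or calc is None:
                continue
            if float(printed) != calc:
                out.append(
                    {
                        "section": r["section"],
                        "stratum": r["stratum"],
                        "column": printed_col,
                        "printed": printed,
                        "recomputed": calc,
                    }
                )
    return out
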