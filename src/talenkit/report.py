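"""Summary statistics tables for mutagenesis experiments.

The layout mirrors the standard reporting of TALEN mutagenesis screens:
counts of embryos with induced mutations per dose, counts per targeted
locus, and germ-line transmission statistics per founder cohort, each
with the fraction expressed as a percentage at one decimal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd


def percent(k: int, n: int) -> float:
    """Percentage k/n at the printed precision (one decimal place)."""
    if n <= 0:
        raise ValueError("denominator must be positive")
    return round(100.0 * k / n, 1)


@dataclass(frozen=True)
class CountRow:
    label: str
    positive: int
    total: int


def contingency_table(rows: Sequence[CountRow]) -> pd.DataFrame:
    """Counts with their percentages, one row per condition."""
    return pd.DataFrame(
        [
            {
                "condition": r.label,
                "n": r.total,
                "positive": r.positive,
                "percent": percent(r.positive, r.total),
            }
            for r in rows
        ]
    )


def transmission_table(
    locus: str,
    n_founders: int,
    n_transmitting: int,
    mean_germline_fraction: float | None,
    mean_distinct_alleles: float | None,
) -> pd.DataFrame:
    """One-locus germ-line transmission summary row."""
    return pd.DataFrame(
        [
            {
                "locus": locus,
                "founders": n_founders,
                "transmitting": n_transmitting,
                "pct_transmitting": percent(n_transmitting, n_founders),
                "mean_germline_mutant_pct": (
                    None
                    if mean_germline_fraction is None
                    else round(100 * mean_germline_fraction, 1)
                ),
                "mean_alleles_per_germline": (
                    None
                    if mean_distinct_alleles is None
                    else round(mean_distinct_alleles, 2)
                ),
            }
        ]
    )
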