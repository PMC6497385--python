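"""Checklist statistics and shared percentage formatting.

All downstream computation keeps full precision; the one-decimal,
round-half-away-from-zero formatting is a presentation concern only.
"""

from __future__ import annotations

import math

import pandas as pd

from .geoio import SpeciesAttributes

__all__ = ["checklist_stats", "area_share", "format_pct"]


def format_pct(value: float, decimals: int = 1) -> float:
    """Round half away from zero (bankers' rounding would drift from the
    conventions used in faunal checklists)."""
    factor = 10 ** decimals
    return math.floor(abs(value) * factor + 0.5) / factor * (1 if value >= 0 else -1)


def checklist_stats(attrs: SpeciesAttributes) -> pd.DataFrame:
    """Counts and percentages of the checklist per national category."""
    if len(attrs) == 0:
        raise ValueError("empty attribute table")
    counts = attrs.category_counts()
    total = int(counts.sum())
    rows = []
    for category in ("CR", "EN", "VU", "NT", "DD", "NA", "LC"):
        n = int(counts.get(category, 0))
        if n == 0 and category not in counts:
            continue
        rows.append({
            "category": category,
            "n_species": n,
            "pct": 100.0 * n / total,
            "pct_formatted": format_pct(100.0 * n / total),
        })
    return pd.DataFrame(rows)


def group_shares(attrs: SpeciesAttributes) -> pd.DataFrame:
    """Species share of each taxonomic group."""
    counts = attrs.table["group"].value_counts()
    total = int(counts.sum())
    return pd.DataFrame({
        "group": counts.index,
        "n_species": counts.values,
        "pct": 100.0 * counts.values / total,
    })


def area_share(part_km2: float, total_km2: float) -> float:
    """Percent of *total* taken by *part*, full precision.

    A part exceeding the total is warned about but still computed.
    """
    if total_km2 <= 0:
        raise ValueError("total area must be positive")
    if part_km2 < 0:
        raise ValueError("part area must be non-negative")
    if part_km2 > total_km2:
        import warnings

        warnings.warn(f"part {part_km2} exceeds total {total_km2}", stacklevel=2)
    return 100.0 * part_km2 / total_km2
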