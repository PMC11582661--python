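"""Descriptive tables: baseline composition and observed transition counts.

Percentages are rounded half-up to one decimal, recomputed from the emitted
counts (never copied from elsewhere), so every printed-style percent equals
``round(100 * count / total, 1)`` cell by cell.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .covariates import (
    BIRTH_AREA_LEVELS,
    ETHNICITY_LEVELS,
    GENDER_LEVELS,
    SLUM_LEVELS,
)
from .data import PanelDataset
from .states import STATE_LABELS, TransitionStructure, default_transition_structure


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round half away from zero at ``ndigits`` decimals (table convention)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


_SUMMARY_VARS = (
    ("slum_area", SLUM_LEVELS),
    ("gender", GENDER_LEVELS),
    ("ethnicity", ETHNICITY_LEVELS),
    ("area_of_birth", BIRTH_AREA_LEVELS),
)


def baseline_summary(roster: pd.DataFrame) -> pd.DataFrame:
    """Composition of the cohort: counts and 1-dp percents per level.

    ``roster`` has one row per individual (first-observation covariates);
    a PanelDataset's records are reduced to first observations automatically.
    An ``Overall`` row carries the total.
    """
    if isinstance(roster, PanelDataset):
        roster = roster.records.groupby("individual_id", sort=False).head(1)
    total = len(roster)
    rows = [{"variable": "Overall", "level": "", "count": total, "percent": 100.0}]
    for var, levels in _SUMMARY_VARS:
        if var not in roster.columns:
            continue
        bad = set(roster[var].unique()) - set(levels)
        if bad:
            raise ValueError(f"unknown {var} level(s): {sorted(map(str, bad))}")
        counts = roster[var].value_counts()
        for level in levels:
            c = int(counts.get(level, 0))
            rows.append({
                "variable": var, "level": level, "count": c,
                "percent": round_half_up(100.0 * c / total, 1),
            })
    return pd.DataFrame(rows)


def summary_from_counts(counts: dict) -> pd.DataFrame:
    """Composition table from pre-tabulated ``level -> count`` of one variable."""
    total = sum(counts.values())
    rows = [{"variable": "Overall", "level": "", "count": total, "percent": 100.0}]
    for level, c in counts.items():
        rows.append({"variable": "counts", "level": level, "count": int(c),
                     "percent": round_half_up(100.0 * c / total, 1)})
    return pd.DataFrame(rows)


def transition_count_table(data: PanelDataset,
                           structure: TransitionStructure | None = None
                           ) -> pd.DataFrame:
    """Observed direct transitions (consecutive differing states) with row %.

    One row per permitted (from, to) pair carrying the count and the percent
    of the origin row's total.  A consecutive pair outside the permitted
    structure raises, listing the pair; same-state consecutive pairs are not
    transitions and are ignored.
    """
    structure = structure or default_transition_structure()
    counts = {pair: 0 for pair in structure.allowed}
    df = data.records
    for _ind, g in data.individuals():
        s = g["state"].to_numpy()
        for a, b in zip(s[:-1], s[1:]):
            if a == b:
                continue
            pair = (int(a), int(b))
            if pair not in structure:
                raise ValueError(
                    f"observed transition {pair[0]}->{pair[1]} "
                    f"({STATE_LABELS[pair[0]]} -> {STATE_LABELS[pair[1]]}) is "
                    "outside the permitted structure"
                )
            counts[pair] += 1
    return transition_table_from_counts(counts, structure)


def transition_table_from_counts(counts: dict,
                                 structure: TransitionStructure | None = None
                                 ) -> pd.DataFrame:
    """Row-percent table from pre-tabulated ``(from, to) -> count``."""
    structure = structure or default_transition_structure()
    row_totals: dict[int, int] = {}
    for (i, _j), c in counts.items():
        row_totals[i] = row_totals.get(i, 0) + int(c)
    rows = []
    for pair in structure.allowed:
        c = int(counts.get(pair, 0))
        tot = row_totals.get(pair[0], 0)
        rows.append({
            "from_state": pair[0], "to_state": pair[1],
            "from": STATE_LABELS[pair[0]], "to": STATE_LABELS[pair[1]],
            "count": c,
            "row_percent": round_half_up(100.0 * c / tot, 1) if tot else float("nan"),
            "formatted": f"{c:,} ({round_half_up(100.0 * c / tot, 1)})" if tot else "-",
        })
    return pd.DataFrame(rows)


def grouped_quantiles(df: pd.DataFrame, value: str, by, qs=(0.25, 0.5, 0.75)
                      ) -> pd.DataFrame:
    """Generic grouped-quantile helper (e.g. median age by calendar year)."""
    out = df.groupby(list(by))[value].quantile(list(qs)).unstack()
    out.columns = [f"q{int(q * 100)}" for q in qs]
    return out.reset_index()
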