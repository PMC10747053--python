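"""Categorical phenotype tabulation by group.

Counts partition the accessions per trait (missing values reported under the
``<missing>`` category); whole-population percentages use only the accessions
phenotyped for that trait and are rounded half-away-from-zero to integers,
the convention of field survey tables.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from sojapop.errors import SojapopError

MISSING_CATEGORY = "<missing>"

SUMMARY_COLUMNS = ["trait", "category", "group", "count", "total", "percent"]


def round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def summarize(table: pd.DataFrame, allowed_groups=None) -> pd.DataFrame:
    """Per-trait, per-category counts by group plus population percentages.

    ``table`` must carry ``accession`` and ``group`` columns; every other
    column is a categorical trait.  ``allowed_groups`` (optional) declares
    the legal group labels; an unknown label raises an error naming it.

    Returns a long-format frame: one row per (trait, category, group) with
    the group count, plus per-category ``total`` and integer ``percent`` of
    the accessions phenotyped for that trait (NaN when nobody is phenotyped).
    """
    if table.empty:
        raise SojapopError("phenotype table is empty")
    for col in ("accession", "group"):
        if col not in table.columns:
            raise SojapopError(f"phenotype table lacks the {col!r} column")
    if table["accession"].duplicated().any():
        dup = table.loc[table["accession"].duplicated(), "accession"].iloc[0]
        raise SojapopError(f"duplicate accession {dup!r}")
    groups = list(dict.fromkeys(table["group"]))
    if allowed_groups is not None:
        unknown = [g for g in groups if g not in set(allowed_groups)]
        if unknown:
            raise SojapopError(f"unknown group label {unknown[0]!r}")
        groups = [g for g in allowed_groups if g in groups]

    traits = [c for c in table.columns if c not in ("accession", "group")]
    rows = []
    for trait in traits:
        vals = table[trait]
        observed = vals.notna() & (vals.astype(str) != "")
        categories = list(dict.fromkeys(vals[observed]))
        n_typed = int(observed.sum())
        for cat in categories + [MISSING_CATEGORY]:
            if cat == MISSING_CATEGORY:
                sel = ~observed
                if not sel.any():
                    continue
            else:
                sel = observed & (vals == cat)
            total = int(sel.sum())
            if cat == MISSING_CATEGORY or n_typed == 0:
                pct = np.nan
            else:
                pct = round_half_away(100.0 * total / n_typed)
            for g in groups:
                rows.append({"trait": trait, "category": cat, "group": g,
                             "count": int((sel & (table["group"] == g)).sum()),
                             "total": total, "percent": pct})
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


def category_total(summary: pd.DataFrame, trait: str, category: str) -> int:
    sub = summary.loc[(summary["trait"] == trait) & (summary["category"] == category)]
    if sub.empty:
        raise SojapopError(f"no category {category!r} for trait {trait!r}")
    return int(sub["total"].iloc[0])


def category_percent(summary: pd.DataFrame, trait: str, category: str):
    sub = summary.loc[(summary["trait"] == trait) & (summary["category"] == category)]
    if sub.empty:
        raise SojapopError(f"no category {category!r} for trait {trait!r}")
    return sub["percent"].iloc[0]
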