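"""Threshold-based selection of differentially expressed genes and target lists.

These are the Venn stages of the pipeline: genes passing significance and
fold-change cuts, targets predicted by enough databases, and exact set
intersections of the resulting lists. All operations are pure functions of
their input tables.
"""

from __future__ import annotations

from typing import Iterable

import pandas as pd


def select_deg(
    table: pd.DataFrame,
    p_thresh: float = 0.05,
    lfc_thresh: float = 1.0,
    use_q: bool = False,
) -> set[str]:
    """Select genes with significance < ``p_thresh`` and |logFC| > ``lfc_thresh``.

    Both inequalities are strict. With ``use_q`` the q-value (FDR) column is
    thresholded instead of the raw p-value; a missing ``qvalue`` column then
    raises a ``ValueError`` naming it.
    """
    col = "qvalue" if use_q else "pvalue"
    if col not in table.columns:
        raise ValueError(f"table has no '{col}' column")
    sig = table[col] < p_thresh
    strong = table["logFC"].abs() > lfc_thresh
    return set(table.loc[sig & strong, "gene"].astype(str))


def intersect_sets(sets: Iterable[set[str]]) -> set[str]:
    """Exact intersection of two or more gene sets (order-independent)."""
    sets = [set(s) for s in sets]
    if len(sets) < 2:
        raise ValueError("need at least 2 sets to intersect")
    out = sets[0]
    for s in sets[1:]:
        out = out & s
    return out


def filter_targets(table: pd.DataFrame, min_databases: int = 3) -> set[str]:
    """Retain genes predicted by at least ``min_databases`` databases (inclusive)."""
    if min_databases < 1:
        raise ValueError("min_databases must be >= 1")
    keep = table["n_databases"] >= min_databases
    return set(table.loc[keep, "gene"].astype(str))


def overlap_targets(degs: set[str], targets: set[str]) -> set[str]:
    """Overlap of the DEG set and the predicted-target set."""
    return set(degs) & set(targets)
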