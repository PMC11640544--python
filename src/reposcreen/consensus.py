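"""Consensus summaries over differential-expression result tables.

Operates on externally produced DE tables (gene, log2FC, p, adjusted p) for
several conditions (cell line x time point): significance filtering at the
standard |log2FC| > 1 and FDR < 0.05 thresholds, exclusive-intersection
(upset) counting across conditions, panel-gene direction/significance
matrices, and monotone-trend flags over ordered time points.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

MAX_UPSET_CONDITIONS = 16


@dataclass
class IntersectionSummary:
    """Exclusive-intersection counts: a partition of the union.

    ``exclusive`` maps every non-empty subset of conditions (as a frozenset)
    to the number of genes significant in exactly that subset; the counts
    sum to ``union_size``.
    """

    conditions: tuple[str, ...]
    exclusive: dict[frozenset, int]
    set_sizes: dict[str, int]
    union_size: int

    def to_frame(self) -> pd.DataFrame:
        rows = [("+".join(sorted(sub)), len(sub), count)
                for sub, count in sorted(self.exclusive.items(),
                                         key=lambda kv: (-kv[1], kv[0]))]
        return pd.DataFrame(rows, columns=["subset", "degree", "exclusive_count"])


@dataclass
class PanelMatrix:
    """Per panel-gene, per condition: fold change, significance, presence."""

    log2fc: pd.DataFrame
    significant: pd.DataFrame
    present: pd.DataFrame


def filter_de(
    table: pd.DataFrame,
    lfc_min: float = 1.0,
    fdr_max: float = 0.05,
) -> set[str]:
    """Genes with |log2FC| > lfc_min and adjusted p < fdr_max (both strict).

    Rows with a missing adjusted p-value are treated as not significant.
    """
    if table.empty:
        return set()
    padj = pd.to_numeric(table["padj"], errors="coerce")
    keep = (table["log2FC"].abs() > lfc_min) & padj.notna() & (padj < fdr_max)
    return set(table.loc[keep, "gene"])


def upset_counts(sets: Mapping[str, set]) -> IntersectionSummary:
    """Exact exclusive-intersection counts by membership-pattern enumeration."""
    conditions = tuple(sets)
    if not conditions:
        raise ValueError("need at least one condition")
    if len(conditions) > MAX_UPSET_CONDITIONS:
        raise ValueError(f"subset enumeration capped at {MAX_UPSET_CONDITIONS} "
                         f"conditions, got {len(conditions)}")
    union = set().union(*sets.values())
    patterns = Counter(
        frozenset(c for c in conditions if g in sets[c]) for g in union)
    exclusive = {
        frozenset(sub): patterns.get(frozenset(sub), 0)
        for r in range(1, len(conditions) + 1)
        for sub in itertools.combinations(conditions, r)
    }
    return IntersectionSummary(
        conditions=conditions,
        exclusive=exclusive,
        set_sizes={c: len(sets[c]) for c in conditions},
        union_size=len(union),
    )


def shared_genes(sets: Mapping[str, set], across: Sequence[str] | None = None
                 ) -> set[str]:
    """Genes present in all (or a named subset of) condition sets."""
    if not sets:
        raise ValueError("need at least one condition")
    names = list(sets) if across is None else list(across)
    unknown = [c for c in names if c not in sets]
    if unknown:
        raise ValueError(f"unknown condition(s): {unknown}")
    out = set(sets[names[0]])
    for c in names[1:]:
        out &= sets[c]
    return out


def panel_matrix(
    tables: Mapping[str, pd.DataFrame],
    panel: Sequence[str],
    lfc_min: float = 1.0,
    fdr_max: float = 0.05,
) -> PanelMatrix:
    """Fold-change / significance matrix for a fixed gene panel.

    A panel gene missing from a condition's table is marked absent (NaN fold
    change, not zero) rather than non-significant.
    """
    panel = list(panel)
    if not panel:
        raise ValueError("panel must be non-empty")
    conds = list(tables)
    lfc = pd.DataFrame(np.nan, index=panel, columns=conds)
    sig = pd.DataFrame(False, index=panel, columns=conds)
    present = pd.DataFrame(False, index=panel, columns=conds)
    for cond, table in tables.items():
        sub = table.set_index("gene")
        hits = filter_de(table, lfc_min=lfc_min, fdr_max=fdr_max)
        for gene in panel:
            if gene in sub.index:
                present.loc[gene, cond] = True
                lfc.loc[gene, cond] = float(sub.loc[gene, "log2FC"])
                sig.loc[gene, cond] = gene in hits
    return PanelMatrix(log2fc=lfc, significant=sig, present=present)


@dataclass
class DirectionConsistency:
    """Monotone-trend flags per gene per cell line, plus per-gene summary."""

    per_line: pd.DataFrame   # columns: gene, cell_line, non_decreasing, non_increasing
    summary: pd.DataFrame    # per gene: counts of lines with each trend


def direction_consistency(
    tables: Mapping[str, pd.DataFrame],
    time_order: Mapping[str, Sequence[str]],
) -> DirectionConsistency:
    """Flag monotone log2FC trends over ordered time points.

    ``time_order`` maps each cell line to its conditions in time order (at
    least two each).  A gene is evaluated in a line only if present at every
    time point of that line; a constant trajectory counts as both
    non-decreasing and non-increasing.
    """
    rows = []
    for line, conds in time_order.items():
        if len(conds) < 2:
            raise ValueError(f"cell line {line!r} has a single time point")
        unknown = [c for c in conds if c not in tables]
        if unknown:
            raise ValueError(f"unknown condition(s): {unknown}")
        series = [tables[c].set_index("gene")["log2FC"] for c in conds]
        genes = set(series[0].index)
        for s in series[1:]:
            genes &= set(s.index)
        for gene in sorted(genes):
            traj = np.array([float(s.loc[gene]) for s in series])
            diffs = np.diff(traj)
            rows.append((gene, line, bool(np.all(diffs >= 0)),
                         bool(np.all(diffs <= 0))))
    per_line = pd.DataFrame(rows, columns=["gene", "cell_line",
                                           "non_decreasing", "non_increasing"])
    summary = per_line.groupby("gene")[["non_decreasing", "non_increasing"]] \
        .sum().rename(columns={"non_decreasing": "n_lines_non_decreasing",
                               "non_increasing": "n_lines_non_increasing"})
    return DirectionConsistency(per_line=per_line, summary=summary)


def load_default_panel() -> list[str]:
    """Canonical and non-canonical NF-kB pathway gene panel shipped with
    the package."""
    text = resources.files("reposcreen").joinpath("data/nfkb_panel.txt") \
        .read_text(encoding="utf-8")
    return [line.strip() for line in text.splitlines()
            if line.strip() and not line.startswith("#")]
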