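"""Target-level association analyses.

Two small analyses around a candidate drug target: (1) compare the target's
expression between a reference subtype and every other subtype with Student
t-tests, and (2) correlate target expression (mRNA or protein) with measured
drug sensitivity (AUC) across cell lines.  Vectors are paired by shared
sample ids; unpaired or missing entries are dropped and counted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffsens import bonferroni_adjust, student_t_test


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float
    n: int
    n_dropped: int
    method: str


def subtype_expression_tests(
    values: pd.Series,
    groups: pd.Series,
    reference: str,
    bonferroni: bool = False,
) -> pd.DataFrame:
    """Test the reference subtype's expression against every other subtype.

    ``effect_size`` is mean(reference) - mean(other); no multiplicity
    correction by default (set ``bonferroni=True`` to add an adjusted
    column).
    """
    groups = groups.reindex(values.index).dropna()
    values = values.loc[groups.index]
    cats = sorted(groups.unique())
    if reference not in cats:
        raise ValueError(f"reference category {reference!r} not present in labels")
    ref_vals = values[groups == reference].dropna().values
    rows = []
    for cat in cats:
        if cat == reference:
            continue
        other = values[groups == cat].dropna().values
        res = student_t_test(other, ref_vals)  # effect = mean(ref) - mean(other)
        rows.append((cat, len(ref_vals), len(other), res.effect_size,
                     res.t_stat, res.df, res.p_value))
    out = pd.DataFrame(rows, columns=["category", "n_reference", "n_category",
                                      "effect_size", "t_stat", "df", "p_value"])
    if bonferroni and len(out):
        out["p_adj"] = bonferroni_adjust(out["p_value"].values)
    return out


def expression_response_correlation(
    x: pd.Series,
    y: pd.Series,
    method: str = "pearson",
) -> CorrelationResult:
    """Correlate two per-sample features paired by shared sample ids.

    Pearson by default (Spearman via ``method``); two-sided p-value from
    the t transform t = r sqrt((n-2)/(1-r^2)).  Requires >= 3 complete
    pairs; a constant vector makes the correlation undefined.
    """
    ids = x.index.union(y.index)
    paired = pd.concat([x.rename("x"), y.rename("y")], axis=1,
                       join="inner").dropna()
    n_dropped = len(ids) - len(paired)
    if len(paired) < 3:
        raise ValueError(f"need >= 3 complete pairs, got {len(paired)}")
    xv, yv = paired["x"].values, paired["y"].values
    if np.ptp(xv) == 0.0 or np.ptp(yv) == 0.0:
        raise ValueError("correlation undefined: a vector is constant")
    if method == "pearson":
        r, p = stats.pearsonr(xv, yv)
    elif method == "spearman":
        r, p = stats.spearmanr(xv, yv)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return CorrelationResult(r=float(r), p_value=float(p), n=len(paired),
                             n_dropped=int(n_dropped), method=method)
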