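"""Subtype-preferential sensitivity testing on imputed drug scores.

Each drug's imputed scores are split by subtype label and compared with a
pooled-variance Student t-test (Welch available behind a flag); p-values are
Bonferroni-corrected over the number of drugs actually tested.  Candidates
are ranked significance-first, then by absolute effect size, so the ranking
reflects both criteria of an effect-size-versus-significance (volcano)
reading.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TTestResult:
    t_stat: float
    df: float
    p_value: float
    effect_size: float  # mean(b) - mean(a)


def student_t_test(a, b) -> TTestResult:
    """Pooled-variance two-sample t-test; effect = mean(b) - mean(a).

    With zero pooled variance the test degenerates: equal means give t=0,
    p=1; unequal means give p=0 with a logged warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    na, nb = a.size, b.size
    effect = float(b.mean() - a.mean())
    df = na + nb - 2
    sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / df
    if sp2 <= 0.0:
        if effect == 0.0:
            return TTestResult(t_stat=0.0, df=float(df), p_value=1.0,
                               effect_size=0.0)
        logger.warning("zero pooled variance with unequal means: p set to 0")
        return TTestResult(t_stat=float(np.sign(effect)) * np.inf,
                           df=float(df), p_value=0.0, effect_size=effect)
    se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    t = effect / se
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return TTestResult(t_stat=float(t), df=float(df), p_value=min(p, 1.0),
                       effect_size=effect)


def welch_t_test(a, b) -> TTestResult:
    """Welch (unequal-variance) alternative with the same conventions."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    effect = float(b.mean() - a.mean())
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va + vb <= 0.0:
        return student_t_test(a, b)
    se2 = va / a.size + vb / b.size
    t = effect / np.sqrt(se2)
    df = se2 ** 2 / (va ** 2 / (a.size ** 2 * (a.size - 1))
                     + vb ** 2 / (b.size ** 2 * (b.size - 1)))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return TTestResult(t_stat=float(t), df=float(df), p_value=min(p, 1.0),
                       effect_size=effect)


def bonferroni_adjust(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni correction: p_adj = min(1, p * m)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size if m is None else int(m)
    if m < 1:
        raise ValueError("number of tests must be >= 1")
    return np.minimum(1.0, p * m)


def run_diffsens(
    scores: pd.DataFrame,
    labels: pd.Series,
    alpha: float = 0.01,
    group_a: str | None = None,
    group_b: str | None = None,
    welch: bool = False,
) -> pd.DataFrame:
    """Per-drug subtype test with Bonferroni correction and ranking.

    ``scores`` is patients x drugs (transformed-AUC scale), ``labels`` maps
    patient id to one of two groups; by default the lexicographically first
    label is group A.  ``effect_size`` is mean(group B) - mean(group A), so
    with AUC-like scores a positive effect means group A is more sensitive.
    Rank 1 is the strongest candidate: significant drugs first, then larger
    |standardized effect| (Cohen's d, comparable across per-drug transformed
    scales), then smaller p, ties broken by drug id.
    """
    labels = labels.reindex(scores.index)
    if labels.isna().any():
        raise ValueError("labels must cover every scored patient")
    groups = sorted(labels.unique())
    if group_a is None and group_b is None:
        if len(groups) != 2:
            raise ValueError(f"expected exactly 2 groups, found {groups}")
        group_a, group_b = groups
    if group_a not in groups or group_b not in groups:
        raise ValueError(f"groups {group_a!r}/{group_b!r} not both present")
    idx_a = labels.index[labels == group_a]
    idx_b = labels.index[labels == group_b]
    if len(idx_a) < 2 or len(idx_b) < 2:
        raise ValueError("each group needs at least 2 patients")

    test = welch_t_test if welch else student_t_test
    rows = []
    for drug in scores.columns:
        a = scores.loc[idx_a, drug].values
        b = scores.loc[idx_b, drug].values
        r = test(a, b)
        pooled_sd = np.sqrt((a.var(ddof=1) * (len(a) - 1)
                             + b.var(ddof=1) * (len(b) - 1))
                            / (len(a) + len(b) - 2))
        d_std = r.effect_size / pooled_sd if pooled_sd > 0 else 0.0
        rows.append((drug, r.effect_size, d_std, r.t_stat, r.df, r.p_value))
    res = pd.DataFrame(rows, columns=["drug", "effect_size",
                                      "effect_size_std", "t_stat", "df",
                                      "p_value"]).set_index("drug")
    res["p_adj"] = bonferroni_adjust(res["p_value"].values)
    res["significant"] = res["p_adj"] < alpha
    # Per-drug monotone transforms make raw mean differences incomparable
    # across drugs, so candidates are ordered by the standardized effect.
    order = res.assign(abs_effect=res["effect_size_std"].abs()) \
        .sort_values(["significant", "abs_effect", "p_value", "drug"],
                     ascending=[False, False, True, True],
                     kind="mergesort")
    res.loc[order.index, "rank"] = np.arange(1, len(res) + 1)
    res["rank"] = res["rank"].astype(int)
    res.attrs["group_a"] = group_a
    res.attrs["group_b"] = group_b
    res.attrs["alpha"] = alpha
    return res


def top_k_overlap(res_a: pd.DataFrame, res_b: pd.DataFrame, k: int = 10
                  ) -> tuple[int, list[str]]:
    """Overlap of the two results' top-k candidates by rank."""
    if k > len(res_a) or k > len(res_b):
        raise ValueError(f"k={k} exceeds the number of ranked drugs")
    top_a = set(res_a.index[res_a["rank"] <= k])
    top_b = set(res_b.index[res_b["rank"] <= k])
    shared = sorted(top_a & top_b)
    return len(shared), shared


def volcano_table(res: pd.DataFrame, p_floor: float = 1e-300) -> pd.DataFrame:
    """Effect-size / significance export: -log10 of the adjusted p-value.

    Adjusted p-values are floored at ``p_floor`` before taking logs, so a
    numerically zero p maps to 300.
    """
    out = pd.DataFrame({
        "drug": res.index,
        "effect_size": res["effect_size"].values,
        "neg_log10_p_adj": -np.log10(np.maximum(res["p_adj"].values, p_floor)),
        "significant": res["significant"].values,
    })
    return out
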