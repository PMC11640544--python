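"""Expression preprocessing: probe collapsing, gene-space alignment,
two-batch empirical-Bayes homogenization, and variance filtering.

The homogenization step implements the parametric empirical-Bayes
location/scale batch adjustment (ComBat): per-gene standardization by the
grand mean and pooled variance, batch location and scale estimates shrunk
toward batch-level priors (normal prior on locations, inverse-gamma prior on
scales, hyperparameters by moment matching, iterative conditional updates to
convergence), then back-transformation to the original scale.  All per-gene
parameters are returned so downstream code and tests can inspect the
adjustment.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TRAIN = "train"
TEST = "test"


class ConvergenceError(RuntimeError):
    """Empirical-Bayes iteration failed to converge."""


class EmptyIntersectionError(ValueError):
    """The two matrices share no genes."""


@dataclass
class CombatParams:
    """Per-gene parameters of the location/scale batch adjustment.

    ``gamma_hat``/``delta2_hat`` are the standardized per-batch location and
    scale estimates; ``gamma_star``/``delta2_star`` their empirical-Bayes
    shrunken counterparts.  DataFrames are genes x batches with columns
    ``train``/``test``.
    """

    grand_mean: pd.Series
    pooled_var: pd.Series
    gamma_hat: pd.DataFrame
    delta2_hat: pd.DataFrame
    gamma_star: pd.DataFrame
    delta2_star: pd.DataFrame
    n_iter: dict[str, int]


@dataclass
class HomogenizedPair:
    """Train and test expression on one identically ordered gene set."""

    train: pd.DataFrame
    test: pd.DataFrame
    params: CombatParams | None = None

    def combined(self) -> pd.DataFrame:
        return pd.concat([self.train, self.test], axis=1)


def collapse_probes(
    probes: pd.DataFrame,
    annotation: pd.DataFrame,
    r_threshold: float = 0.6,
) -> pd.DataFrame:
    """Collapse a probe-level matrix to one row per gene.

    Single-probe genes pass through unchanged.  For multi-probe genes the
    mean pairwise Pearson correlation (on pairwise-complete observations) is
    compared to ``r_threshold``: above it, the probes are averaged (missing
    values excluded); otherwise the probe with the highest mean expression
    is kept.  Unannotated probes are dropped with a warning, as are genes
    whose probes are all missing or that remain incomplete after collapsing.
    """
    if not -1.0 <= r_threshold <= 1.0:
        raise ValueError("r_threshold must lie in [-1, 1]")
    ann = annotation.set_index("probe_id")["gene_symbol"]
    if ann.index.has_duplicates:
        raise ValueError("probe annotation maps a probe more than once")
    unannotated = probes.index.difference(ann.index)
    if len(unannotated):
        logger.warning("dropping %d probes with no gene annotation",
                       len(unannotated))
    usable = probes.loc[probes.index.intersection(ann.index)]

    rows: dict[str, pd.Series] = {}
    for gene, sub in usable.groupby(ann.loc[usable.index]):
        sub = sub.loc[~sub.isna().all(axis=1)]
        if sub.empty:
            logger.warning("gene %s dropped: all probes entirely missing", gene)
            continue
        if len(sub) == 1:
            row = sub.iloc[0]
        else:
            corr = sub.T.corr(min_periods=3)
            vals = corr.values[np.triu_indices(len(sub), k=1)]
            vals = vals[~np.isnan(vals)]
            if len(vals) and float(np.mean(vals)) > r_threshold:
                row = sub.mean(axis=0, skipna=True)
            else:
                row = sub.loc[sub.mean(axis=1, skipna=True).idxmax()]
        if row.isna().any():
            logger.warning("gene %s dropped: missing values remain after "
                           "collapsing", gene)
            continue
        rows[str(gene)] = row
    if not rows:
        raise ValueError("no genes survived probe collapsing")
    out = pd.DataFrame(rows).T.sort_index()
    out.columns = probes.columns
    out.index.name = "gene"
    return out


def intersect_genes(
    train: pd.DataFrame,
    test: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Restrict both matrices to their common genes, lexicographic order."""
    if train.empty or test.empty:
        raise ValueError("cannot intersect an empty matrix")
    common = sorted(set(train.index) & set(test.index))
    if not common:
        raise EmptyIntersectionError("matrices share no genes")
    return train.loc[common], test.loc[common]


def _eb_batch(Z: np.ndarray, conv_tol: float, max_iter: int
              ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, int]:
    """EB shrinkage for one batch of standardized data (genes x samples)."""
    G, n = Z.shape
    gamma_hat = Z.mean(axis=1)
    delta2_hat = ((Z - gamma_hat[:, None]) ** 2).mean(axis=1)

    gamma_bar = gamma_hat.mean()
    tau2 = gamma_hat.var(ddof=1) if G > 1 else 0.0
    V = delta2_hat.mean()
    S2 = delta2_hat.var(ddof=1) if G > 1 else 0.0
    if G < 2 or S2 <= 0.0 or tau2 <= 0.0:
        # Degenerate prior (e.g. a single gene): no shrinkage.
        return gamma_hat, delta2_hat, gamma_hat.copy(), delta2_hat.copy(), 0

    # Inverse-gamma hyperparameters by moment matching.
    a = (2.0 * S2 + V ** 2) / S2
    b = (V * S2 + V ** 3) / S2

    gamma_star = gamma_hat.copy()
    delta2_star = delta2_hat.copy()
    for it in range(1, max_iter + 1):
        g_new = ((n * tau2 * gamma_hat + delta2_star * gamma_bar)
                 / (n * tau2 + delta2_star))
        sse = ((Z - g_new[:, None]) ** 2).sum(axis=1)
        d_new = (b + 0.5 * sse) / (n / 2.0 + a - 1.0)
        change = max(
            np.max(np.abs(g_new - gamma_star) / np.maximum(np.abs(gamma_star), 1.0)),
            np.max(np.abs(d_new - delta2_star) / delta2_star),
        )
        gamma_star, delta2_star = g_new, d_new
        if change < conv_tol:
            return gamma_hat, delta2_hat, gamma_star, delta2_star, it
    raise ConvergenceError(
        f"empirical-Bayes updates did not converge within {max_iter} iterations")


def combat_homogenize(
    train: pd.DataFrame,
    test: pd.DataFrame,
    conv_tol: float = 1e-4,
    max_iter: int = 100,
) -> HomogenizedPair:
    """Two-batch parametric empirical-Bayes batch adjustment.

    Both matrices must already share an identically ordered gene set (see
    :func:`intersect_genes`) and have at least two samples each.  Batch and
    pooled variances use maximum-likelihood (1/n) denominators, which makes
    the adjustment an exact identity when the two batches have equal
    per-gene means and variances.  After adjustment each gene is re-centred
    to its pre-adjustment grand mean.
    """
    if list(train.index) != list(test.index):
        raise ValueError("train and test gene sets must be identical and "
                         "identically ordered; run intersect_genes first")
    if train.shape[1] < 2 or test.shape[1] < 2:
        raise ValueError("each batch needs at least 2 samples")
    genes = train.index
    n1, n2 = train.shape[1], test.shape[1]
    N = n1 + n2
    Y1, Y2 = train.values.astype(float), test.values.astype(float)

    m1, m2 = Y1.mean(axis=1), Y2.mean(axis=1)
    alpha = (n1 * m1 + n2 * m2) / N
    sse = ((Y1 - m1[:, None]) ** 2).sum(axis=1) + ((Y2 - m2[:, None]) ** 2).sum(axis=1)
    sigma2 = sse / N
    if np.any(sigma2 <= 0.0):
        bad = genes[np.where(sigma2 <= 0.0)[0][0]]
        raise ValueError(f"gene {bad!r} has zero pooled variance; filter "
                         "constant genes before homogenizing")
    sigma = np.sqrt(sigma2)

    Z1 = (Y1 - alpha[:, None]) / sigma[:, None]
    Z2 = (Y2 - alpha[:, None]) / sigma[:, None]

    gh1, dh1, gs1, ds1, it1 = _eb_batch(Z1, conv_tol, max_iter)
    gh2, dh2, gs2, ds2, it2 = _eb_batch(Z2, conv_tol, max_iter)

    A1 = (Z1 - gs1[:, None]) / np.sqrt(ds1)[:, None] * sigma[:, None] + alpha[:, None]
    A2 = (Z2 - gs2[:, None]) / np.sqrt(ds2)[:, None] * sigma[:, None] + alpha[:, None]
    # Restore the pre-adjustment grand mean exactly (per-gene constant,
    # identical in both batches).
    pooled = (A1.sum(axis=1) + A2.sum(axis=1)) / N
    A1 += (alpha - pooled)[:, None]
    A2 += (alpha - pooled)[:, None]

    params = CombatParams(
        grand_mean=pd.Series(alpha, index=genes),
        pooled_var=pd.Series(sigma2, index=genes),
        gamma_hat=pd.DataFrame({TRAIN: gh1, TEST: gh2}, index=genes),
        delta2_hat=pd.DataFrame({TRAIN: dh1, TEST: dh2}, index=genes),
        gamma_star=pd.DataFrame({TRAIN: gs1, TEST: gs2}, index=genes),
        delta2_star=pd.DataFrame({TRAIN: ds1, TEST: ds2}, index=genes),
        n_iter={TRAIN: it1, TEST: it2},
    )
    return HomogenizedPair(
        train=pd.DataFrame(A1, index=genes, columns=train.columns),
        test=pd.DataFrame(A2, index=genes, columns=test.columns),
        params=params,
    )


def filter_low_variance(
    pair: HomogenizedPair,
    drop_fraction: float = 0.2,
) -> HomogenizedPair:
    """Drop the lowest-variance genes across the combined samples.

    Variance is computed per gene over train and test samples together; the
    ``floor(drop_fraction * n_genes)`` lowest-variance genes are removed from
    both matrices, ties broken by gene id.
    """
    if not 0.0 <= drop_fraction < 1.0:
        raise ValueError("drop_fraction must lie in [0, 1)")
    combined = pair.combined()
    variances = combined.var(axis=1, ddof=1)
    n_drop = math.floor(drop_fraction * len(variances))
    if n_drop >= len(variances):
        raise ValueError("variance filtering would remove every gene")
    order = np.lexsort((variances.index.astype(str), variances.values))
    drop = set(variances.index[order[:n_drop]])
    keep = [g for g in pair.train.index if g not in drop]
    params = pair.params
    if params is not None:
        params = CombatParams(
            grand_mean=params.grand_mean.loc[keep],
            pooled_var=params.pooled_var.loc[keep],
            gamma_hat=params.gamma_hat.loc[keep],
            delta2_hat=params.delta2_hat.loc[keep],
            gamma_star=params.gamma_star.loc[keep],
            delta2_star=params.delta2_star.loc[keep],
            n_iter=params.n_iter,
        )
    return HomogenizedPair(train=pair.train.loc[keep],
                           test=pair.test.loc[keep], params=params)
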