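"""Per-drug ridge models on cell-line expression and patient imputation.

One model per drug: the training AUC vector is Box-Cox transformed (maximum
likelihood over a lambda grid), genes are standardized on the training
panel, the ridge penalty is chosen by seeded k-fold cross-validation, and
the exact closed-form ridge solution is computed via SVD.  Patients are
scored by applying the stored training standardization and coefficients;
scores stay on the transformed-AUC scale (lower = predicted more
sensitive), since downstream group tests are invariant to the monotone
transform.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

logger = logging.getLogger(__name__)

DEFAULT_LAMBDA_GRID = tuple(np.logspace(-3.0, 5.0, 9))


@dataclass(frozen=True)
class PowerTransformParams:
    """Box-Cox transform parameters: exponent and positivity shift."""

    lam: float
    shift: float = 0.0
    family: str = "box-cox"


@dataclass
class RidgeFit:
    """One fitted ridge model plus the training standardization."""

    beta: np.ndarray            # coefficients on standardized genes
    intercept: float            # mean of the (transformed) response
    gene_means: np.ndarray
    gene_sds: np.ndarray
    lam: float


@dataclass
class DrugModel:
    fit: RidgeFit
    transform: PowerTransformParams | None
    genes: list[str]
    n_lines: int


@dataclass
class RidgeModelBundle:
    """All per-drug models sharing one training gene list."""

    models: dict[str, DrugModel]
    genes: list[str]
    skipped: dict[str, str] = field(default_factory=dict)

    @property
    def drugs(self) -> list[str]:
        return list(self.models)


# ---------------------------------------------------------------------------
# Box-Cox power transform


def boxcox_grid_llf(y: np.ndarray, lams: np.ndarray) -> np.ndarray:
    """Profile log-likelihood of the Box-Cox model on a lambda grid.

    llf(lam) = (lam - 1) * sum(log y) - n/2 * log(var(z(lam))), the Gaussian
    profile likelihood with the Jacobian of the transform; vectorized over
    the grid.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    logy = np.log(y)
    sumlog = logy.sum()
    out = np.empty(len(lams))
    for i, lam in enumerate(lams):
        z = logy if lam == 0.0 else (np.power(y, lam) - 1.0) / lam
        var = z.var()
        out[i] = (lam - 1.0) * sumlog - 0.5 * n * np.log(var)
    return out


def fit_power_transform(
    y: np.ndarray,
    grid_step: float = 0.01,
    grid_range: tuple[float, float] = (-2.0, 2.0),
    eps: float = 1e-6,
) -> PowerTransformParams:
    """Choose the Box-Cox exponent by ML over a grid of lambda values.

    A shift ``max(0, eps - min(y))`` guarantees positivity first.  Requires
    at least 10 finite values; a constant vector is an error (the transform
    likelihood is undefined).
    """
    y = np.asarray(y, dtype=float)
    y = y[~np.isnan(y)]
    if y.size < 10:
        raise ValueError(f"need >= 10 values to fit a power transform, got {y.size}")
    if not np.all(np.isfinite(y)):
        raise ValueError("response contains non-finite values")
    if np.ptp(y) == 0.0:
        raise ValueError("constant response: power transform undefined")
    shift = max(0.0, eps - float(y.min()))
    lams = np.arange(grid_range[0], grid_range[1] + grid_step / 2, grid_step)
    llf = boxcox_grid_llf(y + shift, lams)
    lam = float(lams[int(np.argmax(llf))])
    lam = 0.0 if abs(lam) < grid_step / 2 else round(lam, 10)
    return PowerTransformParams(lam=lam, shift=shift)


def apply_power_transform(y: np.ndarray, params: PowerTransformParams) -> np.ndarray:
    """Standard Box-Cox: ((y+shift)^lam - 1)/lam, log(y+shift) at lam=0."""
    y = np.asarray(y, dtype=float)
    shifted = y + params.shift
    if np.any(shifted <= 0.0):
        raise ValueError("power transform requires y + shift > 0 elementwise")
    if params.lam == 0.0:
        return np.log(shifted)
    return (np.power(shifted, params.lam) - 1.0) / params.lam


# ---------------------------------------------------------------------------
# Ridge regression (exact, SVD-based)


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    means = X.mean(axis=0)
    sds = X.std(axis=0)
    sds = np.where(sds > 0.0, sds, 1.0)
    return (X - means) / sds, means, sds


def _ridge_coefs(U: np.ndarray, s: np.ndarray, Vt: np.ndarray,
                 yc: np.ndarray, lam: float) -> np.ndarray:
    """beta = V diag(s/(s^2+lam)) U' yc, with pseudoinverse cutoff at lam=0."""
    if lam == 0.0:
        cutoff = max(U.shape[0], Vt.shape[1]) * np.finfo(float).eps * (
            s[0] if s.size else 0.0)
        f = np.zeros_like(s)
        mask = s > cutoff
        f[mask] = 1.0 / s[mask]
    else:
        f = s / (s ** 2 + lam)
    return Vt.T @ (f * (U.T @ yc))


def fit_ridge(X: np.ndarray, y: np.ndarray, lam: float) -> RidgeFit:
    """Exact ridge solution on standardized genes.

    Genes are standardized to zero mean / unit variance on the training
    data (stored for patient-side application); the solution
    ``beta = (Z'Z + lam I)^-1 Z'(y - ybar)`` is computed via SVD with
    intercept ``ybar``.
    """
    if lam < 0:
        raise ValueError("ridge penalty must be non-negative")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X must be samples x genes aligned with y")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("missing values must be removed before fitting")
    Z, means, sds = _standardize(X)
    ybar = float(y.mean())
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    beta = _ridge_coefs(U, s, Vt, y - ybar, lam)
    return RidgeFit(beta=beta, intercept=ybar, gene_means=means,
                    gene_sds=sds, lam=float(lam))


class _CVRidge:
    """Per-fold SVD cache so one expression matrix serves many drugs."""

    def __init__(self, X: np.ndarray, k_folds: int, seed: int):
        n = X.shape[0]
        if k_folds < 2 or k_folds > n:
            raise ValueError(f"k_folds must lie in [2, n={n}]")
        self.X = X
        self.folds = []
        kf = KFold(n_splits=k_folds, shuffle=True, random_state=seed)
        for tr, te in kf.split(X):
            if len(tr) < 2:
                raise ValueError("degenerate fold with < 2 training samples")
            Ztr, m, s = _standardize(X[tr])
            U, sv, Vt = np.linalg.svd(Ztr, full_matrices=False)
            Zte_V = ((X[te] - m) / s) @ Vt.T
            self.folds.append((tr, te, U, sv, Zte_V))

    def cv_mse(self, y: np.ndarray, grid: np.ndarray) -> np.ndarray:
        mse = np.zeros(len(grid))
        for tr, te, U, sv, Zte_V in self.folds:
            ytr, yte = y[tr], y[te]
            ybar = ytr.mean()
            w = U.T @ (ytr - ybar)
            for i, lam in enumerate(grid):
                if lam == 0.0:
                    f = np.zeros_like(sv)
                    f[sv > 0] = 1.0 / sv[sv > 0]
                else:
                    f = sv / (sv ** 2 + lam)
                pred = ybar + Zte_V @ (f * w)
                mse[i] += float(np.mean((yte - pred) ** 2))
        return mse / len(self.folds)


def select_lambda(
    X: np.ndarray,
    y: np.ndarray,
    grid=None,
    k_folds: int = 10,
    seed: int = 0,
    _engine: _CVRidge | None = None,
) -> float:
    """Pick the ridge penalty by seeded k-fold cross-validated MSE.

    Ties (and the no-noise limit) resolve to the smallest grid value.
    """
    grid = np.sort(np.asarray(DEFAULT_LAMBDA_GRID if grid is None else grid,
                              dtype=float))
    if grid.size < 2 or np.any(grid < 0):
        raise ValueError("grid must hold >= 2 non-negative values")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    engine = _engine if _engine is not None else _CVRidge(X, k_folds, seed)
    mse = engine.cv_mse(y, grid)
    return float(grid[int(np.argmin(mse))])


# ---------------------------------------------------------------------------
# Per-drug training and patient imputation


def train_all_drugs(
    expr: pd.DataFrame,
    responses: pd.DataFrame,
    min_lines: int = 20,
    lambda_grid=None,
    k_folds: int = 10,
    seed: int = 0,
    power_transform: bool = True,
) -> RidgeModelBundle:
    """Fit one ridge model per drug on homogenized cell-line expression.

    ``expr`` is genes x cell lines, ``responses`` cell lines x drugs (AUC,
    missing entries allowed).  Per drug: missing-response lines are dropped,
    the Box-Cox transform fitted and applied, the penalty cross-validated,
    and the final model fit on all retained lines.  Drugs with fewer than
    ``min_lines`` usable lines are skipped with a logged reason.  Training
    lines are processed in sorted order, making the result invariant to the
    input ordering of cell lines and drugs.
    """
    shared = sorted(set(expr.columns) & set(responses.index))
    if len(shared) < 2:
        raise ValueError("expression and response tables share too few cell lines")
    genes = list(expr.index)
    X_all = expr[shared].T  # lines x genes, sorted line order

    models: dict[str, DrugModel] = {}
    skipped: dict[str, str] = {}
    engines: dict[tuple, tuple[_CVRidge, np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = {}
    grid = np.sort(np.asarray(DEFAULT_LAMBDA_GRID if lambda_grid is None
                              else lambda_grid, dtype=float))
    for drug in sorted(responses.columns):
        y = responses.loc[shared, drug].dropna()
        if len(y) < max(min_lines, k_folds):
            skipped[drug] = f"only {len(y)} usable cell lines (min {min_lines})"
            logger.info("skipping %s: %s", drug, skipped[drug])
            continue
        lines = tuple(y.index)
        yv = y.values.astype(float)
        transform = None
        if power_transform:
            transform = fit_power_transform(yv)
            yv = apply_power_transform(yv, transform)
        key = lines
        if key not in engines:
            Xd = X_all.loc[list(lines)].values
            engine = _CVRidge(Xd, k_folds, seed)
            Z, means, sds = _standardize(Xd)
            U, sv, Vt = np.linalg.svd(Z, full_matrices=False)
            engines[key] = (engine, means, sds, U, sv, Vt)
        engine, means, sds, U, sv, Vt = engines[key]
        lam = float(grid[int(np.argmin(engine.cv_mse(yv, grid)))])
        ybar = float(yv.mean())
        beta = _ridge_coefs(U, sv, Vt, yv - ybar, lam)
        fit = RidgeFit(beta=beta, intercept=ybar, gene_means=means,
                       gene_sds=sds, lam=lam)
        models[drug] = DrugModel(fit=fit, transform=transform, genes=genes,
                                 n_lines=len(y))
    if not models:
        raise ValueError("no drug had enough training cell lines to fit")
    return RidgeModelBundle(models=models, genes=genes, skipped=skipped)


def impute(bundle: RidgeModelBundle, patient_expr: pd.DataFrame) -> pd.DataFrame:
    """Score every patient with every fitted drug model.

    ``patient_expr`` (genes x patients) must contain every training gene;
    genes are standardized with the stored training means/SDs, and the score
    is ``intercept + Z beta`` on the transformed-AUC scale.
    """
    missing = [g for g in bundle.genes if g not in patient_expr.index]
    if missing:
        shown = ", ".join(missing[:10])
        raise ValueError(f"patient matrix lacks {len(missing)} training "
                         f"gene(s): {shown}")
    P = patient_expr.loc[bundle.genes].T.values.astype(float)  # patients x genes
    scores = {}
    for drug, model in bundle.models.items():
        f = model.fit
        Z = (P - f.gene_means) / f.gene_sds
        scores[drug] = f.intercept + Z @ f.beta
    return pd.DataFrame(scores, index=patient_expr.columns)
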