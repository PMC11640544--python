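"""Synthetic screening-study generator with planted ground truth.

Every quantity the downstream pipeline is supposed to recover — causal
coefficients, batch offsets/scales, the subtype-preferential drug — is drawn
here and recorded in :class:`SyntheticTruth`, so each stage can be verified
against an independent oracle (OLS on the causal genes, per-gene batch mean
differences, the generating linear model itself).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import InvalidConfigError, SimulationConfig

SENSITIVE = "sensitive"
OTHER = "other"


@dataclass
class SyntheticTruth:
    """Everything the generator knows and the pipeline must rediscover."""

    gene_means: pd.Series
    gene_sds: pd.Series
    causal_coefficients: dict[str, pd.Series]
    intercepts: pd.Series
    batch_offsets: pd.Series
    batch_scales: pd.Series
    planted_drug: str | None
    planted_effect: float
    subtype_labels: pd.Series | None = field(default=None)

    def implied_response(self, expr: pd.DataFrame) -> pd.DataFrame:
        """Noiseless AUC implied by the generating linear model.

        ``expr`` is a genes x samples matrix on the clean (pre-batch) scale;
        returns samples x drugs.
        """
        out = {}
        for drug, beta in self.causal_coefficients.items():
            x = expr.loc[beta.index]
            out[drug] = self.intercepts[drug] + x.T.values @ beta.values
        return pd.DataFrame(out, index=expr.columns)

    def remove_batch(self, expr: pd.DataFrame) -> pd.DataFrame:
        """Invert the planted location/scale batch distortion exactly."""
        mu = self.gene_means.loc[expr.index]
        off = self.batch_offsets.loc[expr.index]
        sc = self.batch_scales.loc[expr.index]
        return expr.sub(mu + off, axis=0).div(sc, axis=0).add(mu, axis=0)


def _ids(prefix: str, n: int) -> list[str]:
    width = max(3, len(str(n - 1)))
    return [f"{prefix}{i:0{width}d}" for i in range(n)]


def generate_cell_line_panel(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Simulate the training panel: expression, drug screen, and truth.

    Expression entries are log-scale Gaussians with per-gene means and SDs;
    each drug's AUC is ``intercept + sum(beta_g * expression_g) + N(0,
    noise_sd)`` over its causal genes, with the intercept chosen so AUC is
    centred at ``config.auc_center``.  Batch offset/scale parameters for the
    (later) patient batch are drawn here and stored in the truth.

    Returns
    -------
    (expression genes x cell lines, AUC cell lines x drugs, SyntheticTruth)
    """
    rng = np.random.default_rng(config.seed)
    genes = _ids("gene", config.n_genes)
    lines = _ids("line", config.n_cell_lines)
    drugs = _ids("drug", config.n_drugs)

    mu = pd.Series(rng.normal(config.expr_mean_loc, config.expr_mean_scale,
                              config.n_genes), index=genes)
    sd = pd.Series(rng.uniform(config.expr_sd_low, config.expr_sd_high,
                               config.n_genes), index=genes)
    X = mu.values[:, None] + sd.values[:, None] * rng.standard_normal(
        (config.n_genes, config.n_cell_lines))
    expr = pd.DataFrame(X, index=genes, columns=lines)

    coefs: dict[str, pd.Series] = {}
    intercepts = pd.Series(0.0, index=drugs)
    auc = pd.DataFrame(0.0, index=lines, columns=drugs)
    for drug in drugs:
        causal = np.sort(rng.choice(genes, size=config.n_causal_genes_per_drug,
                                    replace=False))
        beta = pd.Series(rng.normal(0.0, config.coef_scale, len(causal)),
                         index=causal)
        intercept = config.auc_center - float(beta.values @ mu.loc[causal].values)
        signal = intercept + expr.loc[causal].T.values @ beta.values
        noise = rng.normal(0.0, config.noise_sd, config.n_cell_lines)
        auc[drug] = signal + noise
        coefs[drug] = beta
        intercepts[drug] = intercept

    offsets = pd.Series(rng.normal(0.0, config.batch_shift_sd, config.n_genes),
                        index=genes)
    scales = pd.Series(np.exp(rng.normal(0.0, config.batch_scale_sd,
                                         config.n_genes)), index=genes)
    planted = (drugs[config.planted_drug_index]
               if config.planted_drug_index is not None else None)
    truth = SyntheticTruth(
        gene_means=mu, gene_sds=sd, causal_coefficients=coefs,
        intercepts=intercepts, batch_offsets=offsets, batch_scales=scales,
        planted_drug=planted, planted_effect=config.planted_effect)
    return expr, auc, truth


def generate_patient_cohort(
    config: SimulationConfig,
    truth: SyntheticTruth,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Simulate a patient cohort sharing the panel's gene space.

    Patients are drawn from the same per-gene marginals, the sensitive
    subtype receives expression shifts on the planted drug's causal genes
    (chosen so the implied response differs by ``planted_effect``), and the
    whole batch is then distorted by the per-gene additive offsets and
    multiplicative scales recorded in ``truth``.

    ``seed`` defaults to ``config.seed + 1`` so panel and cohort draws never
    collide; pass distinct seeds to simulate replicate cohorts from the same
    truth.
    """
    if list(truth.gene_means.index) != list(truth.batch_offsets.index):
        raise ValueError("truth gene sets are inconsistent")
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    genes = list(truth.gene_means.index)
    if len(genes) != config.n_genes:
        raise ValueError("config and truth disagree on the gene set size")
    patients = _ids("patient", config.n_patients)

    mu = truth.gene_means.values[:, None]
    sd = truth.gene_sds.values[:, None]
    clean = mu + sd * rng.standard_normal((config.n_genes, config.n_patients))
    clean = pd.DataFrame(clean, index=genes, columns=patients)

    n_sens = min(max(1, round(config.subtype_fraction * config.n_patients)),
                 config.n_patients - 1)
    sens_idx = rng.permutation(config.n_patients)[:n_sens]
    labels = pd.Series(OTHER, index=patients, name="subtype")
    labels.iloc[sens_idx] = SENSITIVE

    if truth.planted_drug is not None and truth.planted_effect != 0.0:
        beta = truth.causal_coefficients[truth.planted_drug]
        # Minimal-norm expression shift with beta' shift == planted_effect.
        shift = truth.planted_effect * beta / float(beta.values @ beta.values)
        sens_cols = labels.index[labels == SENSITIVE]
        clean.loc[shift.index, sens_cols] = (
            clean.loc[shift.index, sens_cols].add(shift, axis=0))

    mu_s = truth.gene_means
    observed = (clean.sub(mu_s, axis=0)
                .mul(truth.batch_scales, axis=0)
                .add(mu_s + truth.batch_offsets, axis=0))
    truth.subtype_labels = labels
    return observed, labels


def expand_to_probes(
    expr: pd.DataFrame,
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expand a gene-level matrix into redundant probe rows.

    Each gene emits ``config.probes_per_gene`` probe rows equal to the gene
    value plus independent Gaussian probe noise; the annotation maps every
    probe back to its gene.  When ``missing_probe_fraction`` > 0 a random
    subset of probe entries is set missing to exercise NA handling.
    """
    rng = np.random.default_rng(config.seed + 2)
    k = config.probes_per_gene
    probe_ids = [f"{g}_p{i + 1}" for g in expr.index for i in range(k)]
    values = np.repeat(expr.values, k, axis=0)
    if config.probe_noise_sd > 0:
        values = values + rng.normal(0.0, config.probe_noise_sd, values.shape)
    probes = pd.DataFrame(values, index=probe_ids, columns=expr.columns)
    if config.missing_probe_fraction > 0:
        mask = rng.random(probes.shape) < config.missing_probe_fraction
        probes = probes.mask(mask)
    ann = pd.DataFrame({
        "probe_id": probe_ids,
        "gene_symbol": np.repeat(expr.index.values, k),
    })
    return probes, ann


def generate_de_tables(
    n_genes: int = 200,
    n_cell_lines: int = 4,
    n_timepoints: int = 2,
    planted_shared_genes: int = 9,
    seed: int = 0,
    p_pass: float = 0.15,
    lfc_min: float = 1.0,
    fdr_max: float = 0.05,
) -> tuple[dict[str, pd.DataFrame], dict]:
    """Simulate differential-expression result tables with a planted core.

    One table per cell line x time point (conditions named
    ``line{i}_t{j}``).  The ``planted_shared_genes`` first genes pass the
    significance filters (|log2FC| > ``lfc_min`` and adjusted p <
    ``fdr_max``) in *every* table, with log2FC magnitude monotone over time
    within each line; remaining genes pass in a random proper subset of
    tables (never all of them).

    Returns ``(tables, truth)`` where truth records the shared genes and the
    per-line time ordering of condition names.
    """
    if planted_shared_genes > n_genes:
        raise InvalidConfigError("planted_shared_genes exceeds n_genes")
    rng = np.random.default_rng(seed)
    genes = _ids("gene", n_genes)
    shared = genes[:planted_shared_genes]
    lines = [f"line{i + 1}" for i in range(n_cell_lines)]
    tps = [f"t{j + 1}" for j in range(n_timepoints)]
    conditions = [f"{ln}_{tp}" for ln in lines for tp in tps]

    # Decide, per non-shared gene, which conditions it passes in (never all).
    passes = {c: set(shared) for c in conditions}
    for g in genes[planted_shared_genes:]:
        hit = [c for c in conditions if rng.random() < p_pass]
        if len(hit) == len(conditions):
            hit.pop(int(rng.integers(len(hit))))
        for c in hit:
            passes[c].add(g)

    # Shared genes: signed log2FC with magnitude non-decreasing over time.
    sign = rng.choice([-1.0, 1.0], size=len(shared))
    base = rng.uniform(1.2, 2.0, size=(len(shared), n_cell_lines))
    steps = rng.uniform(0.2, 0.8, size=(len(shared), n_cell_lines, n_timepoints))
    steps[:, :, 0] = 0.0
    mag = base[:, :, None] + np.cumsum(steps, axis=2)

    tables: dict[str, pd.DataFrame] = {}
    for li, ln in enumerate(lines):
        for tj, tp in enumerate(tps):
            cond = f"{ln}_{tp}"
            lfc = np.empty(n_genes)
            padj = np.empty(n_genes)
            for gi, g in enumerate(genes):
                if g in shared:
                    lfc[gi] = sign[gi] * mag[gi, li, tj]
                    padj[gi] = 10.0 ** (-rng.uniform(6.0, 30.0))
                elif g in passes[cond]:
                    lfc[gi] = rng.choice([-1.0, 1.0]) * rng.uniform(
                        lfc_min + 0.05, 3.0)
                    padj[gi] = rng.uniform(1e-6, fdr_max * 0.98)
                elif rng.random() < 0.5:
                    lfc[gi] = rng.uniform(-lfc_min, lfc_min)
                    padj[gi] = rng.uniform(0.0, 1.0)
                else:
                    lfc[gi] = rng.normal(0.0, 1.5)
                    padj[gi] = rng.uniform(fdr_max * 1.05, 1.0)
            pvals = padj * rng.uniform(0.1, 1.0, n_genes)  # raw p <= padj
            tables[cond] = pd.DataFrame({
                "gene": genes, "log2FC": lfc, "pvalue": pvals, "padj": padj})
    truth = {
        "shared_genes": shared,
        "conditions": conditions,
        "time_order": {ln: [f"{ln}_{tp}" for tp in tps] for ln in lines},
    }
    return tables, truth
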