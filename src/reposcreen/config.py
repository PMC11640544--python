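"""Configuration for the synthetic screening cohort generator.

The generator emulates the statistical structure the imputation pipeline
assumes: a cell-line training panel (log-scale expression plus a drug screen
whose AUC follows a sparse linear model on expression), and a patient cohort
drawn from the same gene space but observed through an additive/multiplicative
per-gene batch distortion — the location/scale model that empirical-Bayes
batch adjustment targets.  One drug may carry a planted subtype-preferential
sensitivity shift, implemented through causal-gene expression (never by
editing responses directly), so recovering it exercises the full
transcriptome-based pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass


class InvalidConfigError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth parameters for one synthetic screening study.

    Defaults define the reference study conditions used throughout the test
    suite and the analysis scripts: 500 genes, a 200-cell-line training
    panel, a 200-patient cohort, 100 null drugs plus one planted drug whose
    sensitive subtype (25% of patients) has a mean response shift of -1 AUC
    unit (lower AUC = more sensitive).

    Parameters
    ----------
    n_genes, n_cell_lines, n_patients, n_drugs
        Dimensions of the simulated study.
    n_causal_genes_per_drug
        Number of genes with nonzero coefficient in each drug's generating
        linear model.
    coef_scale
        SD of the Gaussian causal coefficients (AUC units per log-expression
        unit).  The default sizes the population response spread
        (~sqrt(n_causal) * coef_scale * mean gene SD ~ 0.34 AUC units) so
        that the planted -1 shift stays detectable after the ~sqrt(n/p)
        attenuation that ridge imputation suffers when training lines are
        fewer than genes; see the methods note.
    auc_center
        Mean AUC about which responses are generated; keeps raw AUC positive.
    noise_sd
        SD of the Gaussian residual added to each generated AUC value.
    batch_shift_sd
        SD of the per-gene additive offset applied to the patient batch.
    batch_scale_sd
        Log-SD of the per-gene multiplicative factor applied to patient
        deviations (scales are exp(N(0, batch_scale_sd^2))).
    subtype_fraction
        Fraction of patients in the sensitive subtype, strictly in (0, 1).
    planted_drug_index
        Index of the drug carrying the subtype effect, or None for a fully
        null cohort.
    planted_effect
        Mean AUC shift of the sensitive subtype for the planted drug
        (negative = more sensitive).
    probes_per_gene, probe_noise_sd, missing_probe_fraction
        Probe-level expansion used to emulate microarray redundancy: each
        gene emits ``probes_per_gene`` probe rows with independent Gaussian
        probe noise; optionally a fraction of probe entries is set missing.
    expr_mean_loc, expr_mean_scale, expr_sd_low, expr_sd_high
        Per-gene marginals: mean ~ N(expr_mean_loc, expr_mean_scale^2),
        SD ~ Uniform(expr_sd_low, expr_sd_high); mimics log2
        microarray/RNA-seq ranges.
    seed
        Base seed; identical seed + config gives bit-identical output.
    """

    n_genes: int = 500
    n_cell_lines: int = 200
    n_patients: int = 200
    n_drugs: int = 101
    n_causal_genes_per_drug: int = 10
    coef_scale: float = 0.12
    auc_center: float = 8.0
    noise_sd: float = 0.1
    batch_shift_sd: float = 1.0
    batch_scale_sd: float = 0.2
    subtype_fraction: float = 0.25
    planted_drug_index: int | None = 0
    planted_effect: float = -1.0
    probes_per_gene: int = 1
    probe_noise_sd: float = 0.3
    missing_probe_fraction: float = 0.0
    expr_mean_loc: float = 7.0
    expr_mean_scale: float = 1.5
    expr_sd_low: float = 0.3
    expr_sd_high: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_cell_lines", "n_patients", "n_drugs",
                     "probes_per_gene"):
            if getattr(self, name) < 1:
                raise InvalidConfigError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.n_causal_genes_per_drug < 0:
            raise InvalidConfigError("n_causal_genes_per_drug must be >= 0")
        if self.n_causal_genes_per_drug > self.n_genes:
            raise InvalidConfigError(
                f"n_causal_genes_per_drug={self.n_causal_genes_per_drug} exceeds "
                f"n_genes={self.n_genes}")
        if not 0.0 < self.subtype_fraction < 1.0:
            raise InvalidConfigError("subtype_fraction must lie strictly in (0, 1)")
        for name in ("coef_scale", "noise_sd"):
            if getattr(self, name) < 0:
                raise InvalidConfigError(f"{name} must be non-negative")
        for name in ("batch_shift_sd", "batch_scale_sd", "probe_noise_sd"):
            if getattr(self, name) < 0:
                raise InvalidConfigError(f"{name} must be non-negative")
        if not 0.0 <= self.missing_probe_fraction < 1.0:
            raise InvalidConfigError("missing_probe_fraction must lie in [0, 1)")
        if self.planted_drug_index is not None and not (
                0 <= self.planted_drug_index < self.n_drugs):
            raise InvalidConfigError("planted_drug_index out of range")
        if self.expr_sd_low <= 0 or self.expr_sd_high < self.expr_sd_low:
            raise InvalidConfigError("require 0 < expr_sd_low <= expr_sd_high")
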