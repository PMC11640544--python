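"""End-to-end synthetic screening runs used by the analysis scripts,
the acceptance script, and the heavier simulation tests."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .config import SimulationConfig
from .diffsens import run_diffsens
from .imputation import RidgeModelBundle, impute, train_all_drugs
from .preprocess import HomogenizedPair, combat_homogenize, filter_low_variance, \
    intersect_genes
from .synthetic import SyntheticTruth, generate_cell_line_panel, \
    generate_patient_cohort


@dataclass
class ScreenResult:
    """Everything one simulated discovery run produced."""

    config: SimulationConfig
    truth: SyntheticTruth
    panel_expr: pd.DataFrame
    auc: pd.DataFrame
    patient_expr: pd.DataFrame
    labels: pd.Series
    pair: HomogenizedPair
    bundle: RidgeModelBundle
    scores: pd.DataFrame
    diffsens: pd.DataFrame

    @property
    def planted_rank(self) -> int | None:
        if self.truth.planted_drug is None:
            return None
        return int(self.diffsens.loc[self.truth.planted_drug, "rank"])

    @property
    def planted_significant(self) -> bool | None:
        if self.truth.planted_drug is None:
            return None
        return bool(self.diffsens.loc[self.truth.planted_drug, "significant"])


def run_screen(
    config: SimulationConfig,
    panel: tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth] | None = None,
    cohort_seed: int | None = None,
    cv_seed: int = 0,
    drop_fraction: float = 0.2,
    alpha: float = 0.01,
    min_lines: int = 20,
    lambda_grid=None,
    k_folds: int = 10,
) -> ScreenResult:
    """Simulate a cohort and run the full imputation + testing pipeline.

    Pass a pre-generated ``panel`` triple (expression, AUC, truth) to reuse
    one training panel across replicate cohorts (``cohort_seed`` then picks
    the cohort draw).
    """
    if panel is None:
        panel = generate_cell_line_panel(config)
    panel_expr, auc, truth = panel
    patient_expr, labels = generate_patient_cohort(config, truth,
                                                   seed=cohort_seed)
    train, test = intersect_genes(panel_expr, patient_expr)
    pair = combat_homogenize(train, test)
    pair = filter_low_variance(pair, drop_fraction)
    bundle = train_all_drugs(pair.train, auc, min_lines=min_lines,
                             lambda_grid=lambda_grid, k_folds=k_folds,
                             seed=cv_seed)
    scores = impute(bundle, pair.test)
    result = run_diffsens(scores, labels, alpha=alpha)
    return ScreenResult(config=config, truth=truth, panel_expr=panel_expr,
                        auc=auc, patient_expr=patient_expr, labels=labels,
                        pair=pair, bundle=bundle, scores=scores,
                        diffsens=result)
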