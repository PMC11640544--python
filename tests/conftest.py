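"""Shared fixtures.

The heavy session fixtures run the full synthetic pipeline at the reference
study conditions (500 genes, 200 cell lines, 101 drugs, 200 patients) over
replicate seeds; several tests consume the summarized outcomes so the
simulations run once per session.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from reposcreen import SimulationConfig, run_screen

N_REPLICATES = 20


def _summarize(res) -> dict:
    clean = res.truth.remove_batch(res.patient_expr)
    true_resp = res.truth.implied_response(clean)
    cors = [float(np.corrcoef(res.scores[d], true_resp[d])[0, 1])
            for d in res.scores.columns]
    return {
        "planted_drug": res.truth.planted_drug,
        "rank": res.planted_rank,
        "significant": res.planted_significant,
        "mean_pearson": float(np.nanmean(cors)),
        "top10": list(res.diffsens.index[res.diffsens["rank"] <= 10]),
    }


@pytest.fixture(scope="session")
def reference_config() -> SimulationConfig:
    return SimulationConfig()


@pytest.fixture(scope="session")
def planted_screen():
    """One full pipeline run at the reference conditions, kept whole."""
    return run_screen(SimulationConfig(seed=1000), cohort_seed=5000, cv_seed=0)


@pytest.fixture(scope="session")
def planted_screen_summaries(reference_config):
    """Planted-drug recovery summaries over the replicate seeds."""
    out = []
    for i in range(N_REPLICATES):
        cfg = replace(reference_config, seed=1000 + i)
        res = run_screen(cfg, cohort_seed=5000 + i, cv_seed=i)
        out.append(_summarize(res))
    return out


@pytest.fixture(scope="session")
def replicate_cohort_pairs(reference_config):
    """Pairs of cohorts simulated from the same truth with different seeds."""
    from reposcreen.synthetic import generate_cell_line_panel

    pairs = []
    for i in range(N_REPLICATES):
        cfg = replace(reference_config, seed=2000 + i)
        panel = generate_cell_line_panel(cfg)
        res_a = run_screen(cfg, panel=panel, cohort_seed=7000 + 2 * i,
                           cv_seed=i)
        res_b = run_screen(cfg, panel=panel, cohort_seed=7001 + 2 * i,
                           cv_seed=i)
        pairs.append((
            res_a.truth.planted_drug,
            list(res_a.diffsens.index[res_a.diffsens["rank"] <= 10]),
            list(res_b.diffsens.index[res_b.diffsens["rank"] <= 10]),
        ))
    return pairs
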