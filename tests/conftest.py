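"""Shared fixtures: small simulated datasets with known ground truth."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from mzdecay import SimConfig, simulate_dataset
from mzdecay.simulate import CLASS_II, TRUTH_COLUMNS, simulate_from_truth


@pytest.fixture(scope="session")
def noisy_sim():
    """9 classes x 40 genes, replicate noise 0.2 log2 units."""
    cfg = SimConfig(n_genes_per_class=40, noise_sd=0.2, seed=42)
    matrix, truth = simulate_dataset(cfg)
    return cfg, matrix, truth


@pytest.fixture(scope="session")
def clean_sim():
    """9 classes x 25 genes, noise-free."""
    cfg = SimConfig(n_genes_per_class=25, noise_sd=0.0, seed=7)
    matrix, truth = simulate_dataset(cfg)
    return cfg, matrix, truth


def exponential_truth(half_lives_min, level: float = 10.0) -> pd.DataFrame:
    """Truth table of purely maternally decaying genes with set half-lives."""
    rows = []
    for i, hl in enumerate(half_lives_min):
        rate = 0.0 if math.isinf(hl) else math.log(2.0) / hl
        rows.append(
            {
                "gene_id": f"g{i:05d}",
                "class_label": CLASS_II,
                "maternal_level_log2": level,
                "maternal_rate": rate,
                "zygotic_rate": 0.0,
                "transcription_gain_log2_per_hr": 0.0,
                "maternal_onset_min": 0.0,
                "zygotic_onset_min": 110.0,
                "transcription_onset_min": 110.0,
                "true_half_life_min": hl,
            }
        )
    return pd.DataFrame(rows, columns=TRUTH_COLUMNS)


def render(truth: pd.DataFrame, noise_sd: float, seed: int):
    cfg = SimConfig(noise_sd=noise_sd, seed=seed)
    return simulate_from_truth(truth, cfg, np.random.default_rng(seed))
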