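"""Shared fixtures: small simulated screens and (expensive) trained models.

Heavy fixtures are session-scoped so one training pays for every test that
needs a fitted model. Sizes are kept at desk scale: a few thousand targets,
depth in the low thousands, compact model configurations.
"""

from __future__ import annotations

import numpy as np
import pytest

import bescreen as bs
from bescreen.perbase import ModelConfig


@pytest.fixture(scope="session")
def abemax_screen():
    """Default-condition ABEmax-like screen (noise on), 800 targets."""
    lib = bs.generate_library(800, seed=42)
    truth = bs.packaged_profiles()["ABEmax-like"]
    cfg = bs.ScreenConfig(n_targets=800, depth_mean=1000, seed=42)
    return bs.simulate_reads(lib, truth, cfg)


@pytest.fixture(scope="session")
def context_dataset():
    """Clean deep ABEmax-like screen -> dichotomized per-base dataset.

    Noise-free and deep so the dichotomized labels reflect the
    window-x-motif truth; motif multipliers != 1 make editing context
    dependent, which is what the per-base model must learn over the
    position-only baseline.
    """
    lib = bs.generate_library(2400, seed=7)
    truth = bs.packaged_profiles()["ABEmax-like"]
    cfg = bs.ScreenConfig(n_targets=2400, depth_mean=1500, n_replicates=2,
                          replicate_noise_sd=0.0, seed=7)
    screen = bs.simulate_reads(lib, truth, cfg)
    counts = bs.pool_replicates(bs.counts_from_screen(screen))
    table = bs.efficiency_table(counts, bs.ABE)
    mean_pct = bs.library_mean_efficiency(table)
    labelled = bs.dichotomize(bs.filter_loci(table, above_mean=False), mean_pct)
    records = {m.record.id: m.record for m in lib}
    dataset = bs.assemble_dataset(labelled, records, n_runs=2, seed=7)
    return screen, counts, dataset


SMALL_CONFIG = ModelConfig(
    embedding_dim=32, n_heads=4, n_encoder_layers=2, feedforward_dim=64,
    dropout_rate=0.1, learning_rate=2e-3, batch_size=256, max_epochs=40,
    early_stop_patience=5, seed=13,
)


@pytest.fixture(scope="session")
def trained_perbase(context_dataset):
    """Per-base models trained on runs 0 and 1 of the context screen."""
    _, _, dataset = context_dataset
    models = {}
    for run in (0, 1):
        models[run], _ = bs.train_perbase(dataset, SMALL_CONFIG, run)
    return dataset, models


@pytest.fixture(scope="session")
def rule_model():
    """Per-base model fitted on the separable preceding-T rule fixture."""
    from helpers import TINY, rule_dataset

    ds = rule_dataset(1200, seed=3)
    model, log = bs.train_perbase(ds, TINY, run=0)
    return ds, model, log


@pytest.fixture(scope="session")
def trained_bystander(context_dataset):
    """Bystander model trained on the edited targets of the context screen."""
    _, counts, dataset = context_dataset
    per_target = dataset.examples.groupby("target_id")["label"].max()
    edited_ids = sorted(per_target.index[per_target == 1])[:700]
    table = bs.empirical_outcome_table(
        [tc for tc in counts if tc.target_id in set(edited_ids)],
        mode="all", min_count=3,
    )
    cfg = ModelConfig(
        embedding_dim=32, n_heads=4, n_encoder_layers=2, feedforward_dim=64,
        dropout_rate=0.1, learning_rate=2e-3, batch_size=256, max_epochs=25,
        early_stop_patience=4, seed=29,
    )
    from bescreen.bystander import split_targets

    splits = split_targets(sorted(table["target_id"].unique()), seed=29)
    model, log = bs.train_bystander(table, dataset.records, cfg, bs.ABE, splits)
    full_table = bs.empirical_outcome_table(
        [tc for tc in counts if tc.target_id in set(edited_ids)], mode="all"
    )
    return model, log, full_table, dataset.records, splits
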