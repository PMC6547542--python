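"""Shared fixtures: small random instances and the default synthetic landscape."""

import numpy as np
import pandas as pd
import pytest

from tfpair import (
    SimulationConfig,
    TagCountTable,
    generate_annotation,
    generate_peak_landscape,
    normalize_tags,
    simulate_tag_counts,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def default_landscape():
    """The default synthetic study: 2,000 peaks, effect fold 4, dispersion 0.1."""
    cfg = SimulationConfig(seed=1)
    annotation = generate_annotation(cfg)
    peaks, truth = generate_peak_landscape(cfg, annotation)
    chip = simulate_tag_counts(peaks, truth, cfg)
    return {
        "config": cfg,
        "annotation": annotation,
        "peaks": peaks,
        "truth": truth,
        "chip": chip,
    }


@pytest.fixture(scope="session")
def wt_classification_table(default_landscape):
    """Jointly normalized WT tag counts for both factors."""
    chip = default_landscape["chip"]
    merged = pd.concat([chip[("tf1", "WT")].data, chip[("tf2", "WT")].data], axis=1)
    return normalize_tags(TagCountTable(merged))


def rep_columns(table, prefix):
    return [c for c in table.sample_ids if c.startswith(prefix)]
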