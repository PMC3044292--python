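"""Shared fixtures: small synthetic panels with planted ground truth."""

import numpy as np
import pandas as pd
import pytest

from gmscreen.synthdata import PanelConfig, generate_panel


@pytest.fixture(scope="session")
def small_panel():
    """A 120-gene, 40-metabolite panel with the default class layout."""
    cfg = PanelConfig(n_genes=120, n_metabolites_known=30, n_metabolites_unknown=10,
                      n_true_pairs=8, n_outlier_pairs=4,
                      informative_gene_fraction=0.3, n_annotation_background=30,
                      seed=11)
    panel, truth = generate_panel(cfg)
    return cfg, panel, truth


@pytest.fixture()
def spike_free_config():
    """Single-class, class-structure-free config: pure-noise background."""
    def make(seed, **overrides):
        base = dict(n_samples=25, class_sizes=(25,), class_names=("panel",),
                    n_genes=15, n_metabolites_known=8, n_metabolites_unknown=4,
                    n_true_pairs=2, n_outlier_pairs=10, outlier_magnitude_sd=8.0,
                    informative_gene_fraction=0.0, missing_rate=0.05,
                    heterogeneous_classes=(), n_annotation_background=0)
        base.update(overrides)
        return PanelConfig(seed=seed, **base)
    return make
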