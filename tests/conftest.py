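"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import pytest

from cytosar.fixtures import default_panel, panel_training_set
from cytosar.validation import kfold_cv, loo_cv


@pytest.fixture(scope="session")
def standard_panel():
    """The default recovery benchmark panel (500 compounds, seed 42)."""
    return default_panel(seed=42)


@pytest.fixture(scope="session")
def standard_training_set(standard_panel):
    return panel_training_set(standard_panel)


@pytest.fixture(scope="session")
def standard_loo(standard_training_set):
    return loo_cv(standard_training_set)


@pytest.fixture(scope="session")
def standard_kfold(standard_training_set):
    return kfold_cv(standard_training_set, k=20, seed=0)
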