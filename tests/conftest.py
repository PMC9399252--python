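"""Shared fixtures: limit-cycle summaries are expensive, so compute once."""

import numpy as np
import pytest

from rreclock.model import (
    DEFAULT_CONFIG,
    Genotype,
    build_model,
    find_limit_cycle,
    simulate,
)
from rreclock.parameters import default_parameters


@pytest.fixture(scope="session")
def wt_model():
    return build_model(Genotype.WT, default_parameters())


@pytest.fixture(scope="session")
def drre_model():
    return build_model(Genotype.DRRE_BMAL1, default_parameters())


@pytest.fixture(scope="session")
def wt_trajectory(wt_model):
    return simulate(wt_model, DEFAULT_CONFIG.t_end)


@pytest.fixture(scope="session")
def wt_summary(wt_model):
    return find_limit_cycle(wt_model)


@pytest.fixture(scope="session")
def drre_summary(drre_model):
    return find_limit_cycle(drre_model)
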