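import numpy as np
import pytest

import delaypop as dp
from delaypop import population as pop


@pytest.fixture(scope="session")
def small_study():
    """A small synthetic study for unit-level checks (6 cells, 4 trials)."""
    return dp.generate_study(
        n_cells=6, velocity=47.2, seed=1, n_trials=4,
        stimulus=dp.StimulusSpec(4.0, 20000.0, 0.0, 300.0, 1.0, 7),
    )


@pytest.fixture(scope="session")
def study20():
    """The 20-cell study used for the population-coding analyses.

    10 s of frozen 0-300 Hz AM noise at 10% contrast, 8 repetitions per
    cell, ground-truth conduction velocity 47.2 m/s.
    """
    return dp.generate_study(
        n_cells=20, velocity=47.2, seed=11, n_trials=8,
        stimulus=dp.StimulusSpec(10.0, 20000.0, 0.0, 300.0, 1.0, 42),
    )


@pytest.fixture(scope="session")
def study20_context(study20):
    """Trial store, alignment delays and cell map for the 20-cell study."""
    return {
        "store": pop.trial_store(study20),
        "align": pop.alignment_delays(study20),
        "cells": {c.cell_id: c.driven_trials for c in study20.cells},
    }
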