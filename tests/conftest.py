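"""Shared fixtures: small synthetic parcellations and a full pipeline run.

Expensive artifacts (the end-to-end study and its connectome/axis outputs)
are session-scoped so many tests can interrogate one run.
"""

import numpy as np
import pytest
from scipy.stats import spearmanr

from axisflux import (
    AnalysisConfig,
    compute_sa_axes,
    session_coherence_fc,
)
from axisflux import synth


@pytest.fixture(scope="session")
def meta20():
    return synth.make_parcellation(20, 4, seed=3)


@pytest.fixture(scope="session")
def meta100():
    return synth.make_parcellation(100, 7, seed=1)


@pytest.fixture(scope="session")
def cycle_cov():
    return synth.simulate_covariates(29, "cycle", seed=7)


@pytest.fixture(scope="session")
def study100():
    """Synthetic 100-parcel, 20-session study with its planted ground truth."""
    meta, truth, cov, records = synth.simulate_study(
        n_parcels=100, n_sessions=20, n_timepoints=512, seed=11
    )
    return meta, truth, cov, records


@pytest.fixture(scope="session")
def pipeline100(study100):
    """Connectomes and aligned axes computed from the synthetic study."""
    meta, truth, cov, records = study100
    fcs = [session_coherence_fc(r) for r in records]
    axes = compute_sa_axes(fcs, meta, AnalysisConfig())
    return meta, truth, cov, fcs, axes


def spearman(a, b):
    return spearmanr(a, b).statistic


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
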