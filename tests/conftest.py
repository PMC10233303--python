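"""Shared fixtures: simulated cohorts at the scales the checks require."""

from types import SimpleNamespace

import numpy as np
import pytest

from resilnet.network import NetworkParams, build_consensus_network
from resilnet.preprocess import PreprocessParams, preprocess_pipeline
from resilnet.simulate import SimDesign, simulate_cohort


@pytest.fixture(scope="session")
def planted_cohort():
    """Full-scale planted cohort run end to end through preprocessing and
    consensus network construction (8 modules, 2000 proteins, 100 cases,
    2 regions)."""
    design = SimDesign(n_cases=100, seed=202)
    matrices, meta, truth = simulate_cohort(design)
    adjusted = {
        r: preprocess_pipeline(m, meta, PreprocessParams(seed=7))[0]
        for r, m in matrices.items()
    }
    shared = None
    for a in adjusted.values():
        shared = a.index if shared is None else shared.intersection(a.index)
    data = {r: a.loc[shared] for r, a in adjusted.items()}
    net = build_consensus_network(data, NetworkParams(seed=7))
    return SimpleNamespace(
        design=design, matrices=matrices, meta=meta, truth=truth,
        data=data, net=net, shared=shared,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Light cohort for unit-level checks."""
    design = SimDesign(
        n_cases=40, n_proteins=400, module_sizes=(60, 50, 40),
        n_batches=10, seed=11,
    )
    matrices, meta, truth = simulate_cohort(design)
    return SimpleNamespace(design=design, matrices=matrices, meta=meta, truth=truth)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
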