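"""Shared fixtures: toy systems, engines and (expensively) trained models.

Everything is generated programmatically and seeded; the session-scoped
model fixture is shared by the Hamiltonian and acceptance tests to keep the
suite inside its runtime budget.
"""

import numpy as np
import pytest

import burnn
from burnn.pipeline import fit_dual_models, refine_models
from burnn.reference import MockQMEngine


@pytest.fixture(scope="session")
def toy50():
    spec = burnn.ToySystemSpec(n_solvent=50)
    topo, config = burnn.build_toy_system(spec, seed=1)
    return topo, config


@pytest.fixture(scope="session")
def toy_small():
    spec = burnn.ToySystemSpec(n_solvent=8)
    topo, config = burnn.build_toy_system(spec, seed=2)
    return topo, config


@pytest.fixture(scope="session")
def engine50(toy50):
    topo, _ = toy50
    return MockQMEngine(topo)


@pytest.fixture(scope="session")
def engine_small(toy_small):
    topo, _ = toy_small
    return MockQMEngine(topo)


@pytest.fixture(scope="session")
def trained_models(toy50, engine50):
    """Delta/intra committees for both end states, adaptively refined.

    Expensive (a few minutes); shared across the Hamiltonian and acceptance
    tests.  Also returns an equilibrated starting configuration.
    """
    topo, config = toy50
    models = fit_dual_models(topo, config, engine50, seed=3, n_frames=300,
                             cadence=5, mm_cutoff=1.0)
    start = models["frames"][40].copy()
    start.velocities = None
    models = refine_models(topo, start, models, engine50, seed=9, rounds=2,
                           probe_steps=250, mm_cutoff=1.0)
    return models, start
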