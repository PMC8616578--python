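"""Shared fixtures: one synthetic session with all five archetypes.

Expensive objects (session, design matrix, GLM fits) are session-scoped
so the whole suite reuses them.
"""

import numpy as np
import pytest

import ofc_encoding as oe


@pytest.fixture(scope="session")
def task_config():
    return oe.TaskConfig(n_trials=150, seed=7)


@pytest.fixture(scope="session")
def session(task_config):
    return oe.generate_session(task_config, seed=7)


@pytest.fixture(scope="session")
def basis():
    return oe.build_basis()


@pytest.fixture(scope="session")
def design(session, basis):
    return oe.build_design_matrix(session, basis=basis)


@pytest.fixture(scope="session")
def scheme(session):
    return oe.partition_trials(session, seed=0)


@pytest.fixture(scope="session")
def archetype_neurons(task_config, basis):
    return oe.make_archetypes(task_config, seed=3, basis=basis)


@pytest.fixture(scope="session")
def archetype_spikes(session, archetype_neurons, basis):
    return [oe.simulate_spikes(session, n, seed=40 + i, basis=basis)
            for i, n in enumerate(archetype_neurons)]


@pytest.fixture(scope="session")
def archetype_fits(archetype_spikes, design):
    """Moderate fixed-ridge fits with kernel covariance, one per archetype."""
    return [oe.fit_glm(sp.binned_counts, design, xi=1.0, compute_cov=True)
            for sp in archetype_spikes]


@pytest.fixture(scope="session")
def null_neuron(basis):
    from ofc_encoding.task import GroundTruthNeuron
    return GroundTruthNeuron(archetype="null", kernel_weights={},
                             background=float(np.log(5.0 * basis.dt)),
                             unit_id="null_unit")


@pytest.fixture(scope="session")
def null_spikes(session, null_neuron, basis):
    return oe.simulate_spikes(session, null_neuron, seed=99, basis=basis)
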