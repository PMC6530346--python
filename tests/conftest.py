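import numpy as np
import pytest

from dige_mm import (
    AnnotationTable,
    ContaminationSpec,
    DesignTable,
    Group,
    SimulationConfig,
    SpotAnnotation,
    SpotClass,
    SpotMatrix,
    simulate_experiment,
)


@pytest.fixture(scope="session")
def sim_default():
    """One default-condition experiment (effects + contamination confound)."""
    return simulate_experiment(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def sim_null():
    """Global-null experiment: no effects, no group-shifted contamination."""
    return simulate_experiment(SimulationConfig.null(seed=11))


@pytest.fixture
def tiny_matrix():
    """3 spots x 2 gels, handy for exact arithmetic checks."""
    return SpotMatrix(
        ["s1", "s2", "s3"],
        ["gelA", "gelB"],
        sample=np.array([[10.0, 20.0], [30.0, 40.0], [50.0, 60.0]]),
        ips=np.array([[11.0, 21.0], [31.0, 41.0], [51.0, 61.0]]),
    )


def make_annotation(spot_ids, classes, accessions=None, genes=None):
    accessions = accessions or [None] * len(spot_ids)
    genes = genes or [None] * len(spot_ids)
    return AnnotationTable(
        [
            SpotAnnotation(s, a, g, c)
            for s, a, g, c in zip(spot_ids, accessions, genes, classes)
        ]
    )


def make_design(n_per_group=(2, 2, 2, 2, 2)):
    groups = {}
    i = 0
    for g, n in zip(Group, n_per_group):
        for _ in range(n):
            i += 1
            groups[f"gel{i:02d}"] = g
    return DesignTable(groups)


@pytest.fixture
def small_design():
    return make_design()
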