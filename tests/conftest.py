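import numpy as np
import pandas as pd
import pytest

from srnakit import classifier as clf
from srnakit import features as feat
from srnakit import simulate as sim
from srnakit.annotate import hierarchical_annotate, preprocess


@pytest.fixture(scope="session")
def hairpin_sets():
    """Labelled real/pseudo hairpin training sets (200 + 200, fixed seed)."""
    return sim.generate_hairpin_sets(200, 200, seed=7)


@pytest.fixture(scope="session")
def hairpin_matrix(hairpin_sets):
    pos, neg = hairpin_sets
    matrix = pd.concat([feat.feature_matrix(pos), feat.feature_matrix(neg)])
    labels = np.array([1] * len(pos) + [-1] * len(neg))
    return matrix, labels


@pytest.fixture(scope="session")
def trained_model(hairpin_matrix):
    matrix, labels = hairpin_matrix
    return clf.train(matrix, labels, seed=7)


@pytest.fixture(scope="session")
def pipeline_fixture():
    """Full eight-stage toy small-RNAome, 50,000 reads per stage."""
    return sim.generate(sim.FixtureSpec(seed=11))


@pytest.fixture(scope="session")
def annotated_fixture(pipeline_fixture):
    retained, qc = preprocess(pipeline_fixture.tags)
    assignments = hierarchical_annotate(retained, pipeline_fixture.references)
    return retained, qc, assignments


@pytest.fixture(scope="session")
def random_structure_bank():
    return sim.random_structures(1000, seed=5)
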