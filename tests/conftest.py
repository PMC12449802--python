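import numpy as np
import pytest

import magselect as m


@pytest.fixture
def tiny_matrix():
    """3 genomes x 4 samples (2 disease, 1 healthy, 1 excluded)."""
    return m.AbundanceMatrix(
        ["g1", "g2", "g3"],
        ["d1", "d2", "h1", "a1"],
        np.array([
            [2.0, 4.0, 1.0, 9.0],
            [0.0, 0.0, 0.0, 0.0],
            [1.0, 1.0, 5.0, 9.0],
        ]),
    )


@pytest.fixture
def tiny_metadata():
    return [
        m.SampleMetadata("d1", "disease"),
        m.SampleMetadata("d2", "disease"),
        m.SampleMetadata("h1", "healthy"),
        m.SampleMetadata("a1", "excluded"),
    ]


@pytest.fixture(scope="session")
def small_cohort():
    """A small planted cohort shared by cheaper downstream tests."""
    spec = m.SyntheticSpec(
        n_disease=30, n_healthy=30, n_genomes=60, frac_differential=0.1,
        effect_log2fc=2.0, low_abundance_bias=0.9, seed=7,
    )
    matrix, metadata, records, truth = m.generate_cohort(spec)
    return spec, matrix, metadata, records, truth


def labels_for(matrix, metadata):
    by_id = {s.sample_id: s.status for s in metadata}
    return np.array(
        [1 if by_id[s] == "disease" else 0 for s in matrix.sample_ids]
    )
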