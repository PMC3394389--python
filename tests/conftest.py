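import numpy as np
import pytest

from eigfusion import ExpressionMatrix, SampleLabels


@pytest.fixture
def worked_matrix():
    """5 genes x 8 samples; S1 = last four samples.

    Gene g1 is the hand-worked transformation example (1..8); gene g5 has the
    matrix maximum u = 8 added to 2 of its 4 cancer samples (a spiked outlier
    gene), g2/g4 are group-symmetric (zero score), g3 is near-symmetric.
    """
    base = np.array(
        [
            [1, 2, 3, 4, 5, 6, 7, 8],
            [2, 1, 2, 3, 2, 1, 2, 3],
            [5, 4, 6, 5, 4, 6, 5, 4],
            [1, 3, 1, 3, 1, 3, 1, 3],
            [2, 2, 3, 1, 2, 3, 2, 1],
        ],
        dtype=float,
    )
    spiked = base.copy()
    spiked[4, 4] += base.max()
    spiked[4, 5] += base.max()
    samples = [f"s{j}" for j in range(1, 9)]
    return ExpressionMatrix([f"g{i}" for i in range(1, 6)], samples, spiked)


@pytest.fixture
def worked_labels(worked_matrix):
    samples = worked_matrix.sample_ids
    return SampleLabels(samples[4:], samples[:4])


@pytest.fixture
def random_matrix_factory():
    """Random dense matrices with unique IDs, for oracle comparisons."""

    def make(n_genes, n_samples, seed=0, scale=1.0):
        rng = np.random.default_rng(seed)
        values = rng.normal(0.0, scale, (n_genes, n_samples))
        return ExpressionMatrix(
            [f"g{i}" for i in range(n_genes)],
            [f"s{j}" for j in range(n_samples)],
            values,
        )

    return make
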