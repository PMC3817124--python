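import numpy as np
import pytest

from popstruct.data import GenotypeMatrix, make_marker_table, make_sample_table


def toy_matrix(calls, rs_ids=None, sample_ids=None, **marker_kwargs) -> GenotypeMatrix:
    """Build a small GenotypeMatrix from a nested list of calls."""
    calls = np.asarray(calls, dtype=np.int16)
    n, l = calls.shape
    rs_ids = rs_ids or [f"rs{j + 1}" for j in range(l)]
    sample_ids = sample_ids or [f"S{i + 1}" for i in range(n)]
    return GenotypeMatrix(
        calls,
        make_marker_table(rs_ids, **marker_kwargs),
        make_sample_table(sample_ids),
    )


@pytest.fixture
def two_pop_matrix():
    """Two clearly differentiated populations of 4 individuals each."""
    calls = [
        [0, 0, 1, 0],
        [0, 1, 0, 0],
        [1, 0, 0, 1],
        [0, 0, 1, 0],
        [2, 2, 1, 2],
        [2, 1, 2, 2],
        [1, 2, 2, 1],
        [2, 2, 2, 2],
    ]
    return toy_matrix(calls)
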