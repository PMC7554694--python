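import numpy as np
import pytest

from spcount import SpectralCountMatrix


def make_matrix(counts, lengths=None, groups=("test", "ref")):
    """Build a two-group matrix from a counts array; half the runs per group."""
    counts = np.asarray(counts)
    n_prot, n_runs = counts.shape
    if lengths is None:
        lengths = np.full(n_prot, 300)
    half = n_runs // 2
    run_ids = [f"{groups[0]}_r{i}" for i in range(half)] + [
        f"{groups[1]}_r{i}" for i in range(n_runs - half)
    ]
    group_map = {r: (groups[0] if i < half else groups[1])
                 for i, r in enumerate(run_ids)}
    return SpectralCountMatrix(
        accessions=[f"P{i:04d}" for i in range(n_prot)],
        lengths=np.asarray(lengths),
        counts=counts,
        run_ids=run_ids,
        groups=group_map,
    )


@pytest.fixture
def small_matrix():
    """4 proteins x 6 runs (3 per group) with varied presence patterns."""
    counts = np.array([
        [10, 12, 11, 10, 11, 12],   # common, similar
        [40, 44, 38, 10, 12, 11],   # common, higher in test
        [5, 6, 4, 0, 0, 0],         # unique to test group
        [0, 0, 0, 9, 8, 10],        # unique to ref group
    ])
    return make_matrix(counts)
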