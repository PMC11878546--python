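import numpy as np
import pytest

from mitocall import AlleleCountTensor, CloneSimSpec, simulate_dataset


@pytest.fixture
def small_tensor() -> AlleleCountTensor:
    """3 cells x 5 loci with mixed bases, including a zero-count locus."""
    rng = np.random.default_rng(123)
    counts = rng.integers(0, 20, size=(4, 3, 5))
    counts[:, :, 4] = 0
    return AlleleCountTensor(
        cells=["AAA-1", "CCC-1", "GGG-1"],
        loci=[("chrM", p) for p in (10, 20, 30, 40, 50)],
        counts=counts,
    )


@pytest.fixture
def planted_clone():
    """200 cells, 10 loci at depth ~50; 20-cell clone at locus 3, heteroplasmy 0.7."""
    spec = CloneSimSpec(
        n_cells=200,
        n_loci=10,
        depth_log_mean=float(np.log(50)),
        depth_log_sd=0.3,
        planted={3: (list(range(20)), 0.7)},
        seed=7,
    )
    return simulate_dataset(spec)
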