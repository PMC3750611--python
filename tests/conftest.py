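import numpy as np
import pytest

from radcomp import DEFAULT_STEP, DifferentialDVH, load_builtin, normalize_volumes


def random_dvh(rng: np.random.Generator, step: float = DEFAULT_STEP) -> DifferentialDVH:
    """Random normalized differential DVH on a grid aligned to ``step``."""
    n_bins = int(rng.integers(4, 240))
    edges = step * np.arange(n_bins + 1)
    vols = rng.random(n_bins) ** 3  # sparse-ish occupancy
    vols[rng.random(n_bins) < 0.5] = 0.0
    if vols.sum() == 0:
        vols[int(rng.integers(n_bins))] = 1.0
    return normalize_volumes(DifferentialDVH(edges, vols))


@pytest.fixture(scope="session")
def builtin_sets():
    return load_builtin()


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
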