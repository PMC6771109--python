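import numpy as np
import pytest

from atlas_smooth.spatial_structure import adjacency_from_edges, repair_islands
from atlas_smooth.synthetic_data import SyntheticConfig, generate_lattice_geography


@pytest.fixture
def chain3():
    """3-area chain graph A - B - C."""
    return adjacency_from_edges(
        [("A", "B"), ("B", "C")],
        ["A", "B", "C"],
        centroids=np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]]),
    )


@pytest.fixture
def lattice_4x5():
    cfg = SyntheticConfig(grid_rows=4, grid_cols=5, n_islands=0)
    return generate_lattice_geography(cfg)


@pytest.fixture
def lattice_with_islands():
    cfg = SyntheticConfig(grid_rows=4, grid_cols=4, n_islands=2)
    return generate_lattice_geography(cfg)


@pytest.fixture
def repaired_10x10():
    cfg = SyntheticConfig(grid_rows=10, grid_cols=10, n_islands=1)
    return repair_islands(generate_lattice_geography(cfg))


def ess(x: np.ndarray) -> float:
    """Effective sample size via the initial positive autocorrelation sum."""
    x = np.asarray(x, dtype=float)
    x = x - x.mean()
    n = x.size
    denom = float(x @ x)
    if denom == 0:
        return float(n)
    acf = np.correlate(x, x, "full")[n - 1:] / denom
    s = 1.0
    for k in range(1, n // 3):
        if acf[k] <= 0:
            break
        s += 2.0 * acf[k]
    return n / s


def mc_se(x: np.ndarray) -> float:
    """Monte-Carlo standard error accounting for autocorrelation."""
    return float(np.std(x) / np.sqrt(ess(x)))
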