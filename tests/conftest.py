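import numpy as np
import pandas as pd
import pytest

from synovniche import simulate


@pytest.fixture
def six_cell_fixture() -> pd.DataFrame:
    """Six collinear cells in one FOV with hand-checkable distances."""
    return pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(6)],
            "sample_id": "s1",
            "fov_id": "f1",
            "x_um": [0.0, 1.0, 2.0, 10.0, 11.0, 12.0],
            "y_um": [0.0] * 6,
            "cell_type": ["A", "A", "B", "B", "B", "A"],
        }
    )


@pytest.fixture
def if_panel() -> pd.DataFrame:
    return simulate.default_if_panel()


@pytest.fixture
def small_tissue() -> pd.DataFrame:
    """2,000-cell two-niche bands tissue with exclusive types."""
    config = simulate.TissueConfig(
        n_cells=2000,
        composition=np.array([[1.0, 0.0], [0.0, 1.0]]),
        cell_types=["A", "B"],
        n_niches=2,
        niche_layout="bands",
        fov_grid=(1, 2),
        fov_size_um=300.0,
        seed=7,
    )
    return simulate.generate_tissue(config)


def brute_force_knn(cells: pd.DataFrame, i: int, k: int) -> list[int]:
    """Exhaustive pairwise-distance kNN with (distance, cell_id) tie-break."""
    xi, yi = cells["x_um"].iloc[i], cells["y_um"].iloc[i]
    dists = []
    for j in range(len(cells)):
        if j == i:
            continue
        d = np.hypot(cells["x_um"].iloc[j] - xi, cells["y_um"].iloc[j] - yi)
        dists.append((d, cells["cell_id"].iloc[j], j))
    dists.sort()
    return [j for _, _, j in dists[:k]]
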