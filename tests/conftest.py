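import numpy as np
import pytest

import spotdiff as sd


@pytest.fixture(scope="session")
def lattice_3x3():
    return sd.build_grid(sd.rectilinear_lattice(3, 3), "rectilinear", spacing=1.0)


@pytest.fixture(scope="session")
def lattice_5x5():
    return sd.build_grid(sd.rectilinear_lattice(5, 5), "rectilinear", spacing=1.0)


@pytest.fixture(scope="session")
def lattice_9x9():
    return sd.build_grid(sd.rectilinear_lattice(9, 9), "rectilinear", spacing=1.0)


@pytest.fixture(scope="session")
def lattice_20x20():
    return sd.build_grid(sd.rectilinear_lattice(20, 20), "rectilinear", spacing=1.0)


@pytest.fixture(scope="session")
def hex_lattice_5x5():
    return sd.build_grid(sd.hexagonal_lattice(5, 5), "hexagonal", spacing=1.0)


@pytest.fixture(scope="session")
def blob_fixture(lattice_20x20):
    """Two disjoint spatial blobs; 10 genes express blob A, 10 blob B.

    Small multiplicative noise on top of a strong indicator signal, so the
    leading principal components separate the two blob indicators.
    """
    grid = lattice_20x20
    rng = np.random.default_rng(42)
    blob_a = np.linalg.norm(grid.coords - np.array([5.0, 10.0]), axis=1) < 4.0
    blob_b = np.linalg.norm(grid.coords - np.array([14.0, 10.0]), axis=1) < 4.0
    profiles, labels = [], []
    for i in range(20):
        blob = blob_a if i < 10 else blob_b
        amp = rng.uniform(20, 60)
        counts = np.where(blob, amp, 0.0)
        counts = np.rint(counts * rng.uniform(0.95, 1.05, grid.n_locations))
        profiles.append(counts)
        labels.append(0 if i < 10 else 1)
    matrix = sd.ProfileMatrix.from_raw(
        np.vstack(profiles), [f"g{i:02d}" for i in range(20)]
    )
    return grid, matrix, np.array(labels), blob_a, blob_b
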