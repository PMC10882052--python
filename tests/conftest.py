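import numpy as np
import pandas as pd
import pytest

from zonescope import reads, syndata


@pytest.fixture(scope="session")
def txome():
    return syndata.make_toy_transcriptome(n_genes=60, min_len=300, seed=11)


@pytest.fixture(scope="session")
def scheme():
    return reads.BarcodeScheme.default(n_cells=24)


@pytest.fixture(scope="session")
def clean_run(scheme, txome):
    """Error-free tDISCO run: no barcode errors, no UMI duplication."""
    return syndata.simulate_tdisco_run(
        scheme,
        txome,
        cells_per_zone=3,
        reads_per_cell=120,
        umi_dup_rate=0.0,
        bc_error_rate=0.0,
        seed=21,
    )


@pytest.fixture(scope="session")
def visium():
    counts, coords, truth = syndata.simulate_visium_section(
        n_rows=20, n_cols=20, n_genes=90, k_true=3, injury_radius=3, seed=31
    )
    return counts, coords, truth


@pytest.fixture()
def hex_lattice_small():
    from zonescope import spatial

    coords = syndata.hex_lattice(6, 6)
    return spatial.build_adjacency(coords)


def moran_bruteforce(values: np.ndarray, adjacency) -> float:
    """O(n^2) double-sum oracle for global Moran's I with binary weights."""
    w = adjacency.toarray()
    z = np.asarray(values, dtype=float)
    z = z - z.mean()
    num = sum(
        w[i, j] * z[i] * z[j] for i in range(len(z)) for j in range(len(z))
    )
    return len(z) / w.sum() * num / (z**2).sum()
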