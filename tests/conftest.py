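"""Shared fixtures: small synthetic data sets and matrix builders."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from scredit.config import SimulationConfig
from scredit.matrix import EditingMatrix
from scredit.simulate import simulate_dataset


def make_matrix(alt, depth, sites=None, cells=None, **site_cols):
    """EditingMatrix from dense arrays with minimal metadata."""
    alt = np.asarray(alt)
    depth = np.asarray(depth)
    n_sites, n_cells = depth.shape
    if sites is None:
        sites = pd.DataFrame(
            {
                "site_id": [f"s{i}" for i in range(n_sites)],
                "chrom": "chr1",
                "pos": np.arange(1, n_sites + 1) * 100,
                "ref": "A",
                "alt": "G",
            }
        )
        for k, v in site_cols.items():
            sites[k] = v
    if cells is None:
        cells = pd.DataFrame({"cell_id": [f"c{j}" for j in range(n_cells)]})
    depth_sp = sp.csr_matrix(depth)
    alt_sp = depth_sp.copy()
    alt_sp.data = alt[depth > 0]
    return EditingMatrix(sites, cells, alt_sp, depth_sp)


@pytest.fixture(scope="session")
def small_config():
    # transcription rate raised so sites reach the 10-cell prevalence
    # threshold at this small cell count
    return SimulationConfig(
        n_cells=80, n_sites=200, n_genes=25, transcription_rate=0.3, seed=7
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)
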