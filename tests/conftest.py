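import os
import sys

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, os.path.dirname(__file__))

from seqfishkit import Codebook, Codeword, generate_codebook


@pytest.fixture(scope="session")
def codebook50():
    """50 genes, 4 rounds, palette 12, min Hamming distance 3."""
    return generate_codebook(50, rounds=4, palette_size=12, min_hamming=3, seed=1)


@pytest.fixture(scope="session")
def codebook_small():
    """20 genes over a small palette; still single-error correcting."""
    return generate_codebook(20, rounds=4, palette_size=6, min_hamming=3, seed=2)


@pytest.fixture()
def tie_codebook():
    """Hand-built min_hamming=2 codebook admitting distance-1 ties."""
    return Codebook(
        rounds=4,
        palette_size=3,
        min_hamming=2,
        codewords=[
            Codeword("gA", (1, 1, 1, 1)),
            Codeword("gB", (1, 1, 2, 2)),
            Codeword("gC", (2, 2, 1, 1)),
        ],
    )


def grid_truth(n, spacing, genes, fov=0, origin=10.0):
    """Ground-truth transcripts on a square grid, cycling through `genes`."""
    cols = int(np.ceil(np.sqrt(n)))
    rows = [
        (
            i,
            genes[i % len(genes)],
            fov,
            origin + (i % cols) * spacing,
            origin + (i // cols) * spacing,
            None,
        )
        for i in range(n)
    ]
    return pd.DataFrame(
        rows, columns=["transcript_id", "gene_id", "fov", "x", "y", "cell_id"]
    )


@pytest.fixture()
def make_grid_truth():
    return grid_truth
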