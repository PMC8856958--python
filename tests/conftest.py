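import numpy as np
import pytest

import shmirkit as sk


@pytest.fixture(scope="session")
def planted_txome():
    """Transcriptome with planted off-target runs of 14-17 nt.

    Returns (transcriptome, truth, spec); candidate starts 100/200/300/400
    (inside the shared CDS, which begins at position 90 of the reference)
    carry runs of lengths 14, 15, 16, 17 respectively.
    """
    spec = sk.TxomeSpec(
        n_decoys=40,
        decoy_length=400,
        cds_length=600,
        planted_runs=((100, 14), (200, 15), (300, 16), (400, 17)),
        seed=11,
    )
    txome, truth = sk.make_transcriptome(spec)
    return txome, truth, spec


@pytest.fixture(scope="session")
def cell_sim():
    """A medium-size simulated co-expression dataset (default conditions)."""
    spec = sk.CoexprSpec(seed=7)
    cells, regions, truth = sk.simulate_cell_table(spec)
    return cells, regions, truth, spec


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
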