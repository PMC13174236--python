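import numpy as np
import pytest
import scipy.sparse as sp

from hicrearr.genome import BinIndex, GenomeLayout, toy_layout
from hicrearr.matrix import ContactMatrix, balance_sqrt_vc
from hicrearr.simulate import default_config, simulate_hic, synth_tracks


@pytest.fixture(scope="session")
def layout():
    return toy_layout()


@pytest.fixture(scope="session")
def default_sim():
    """One default-condition simulation shared across read-only tests."""
    cfg = default_config(seed=11)
    mats, truth = simulate_hic(cfg, resolutions=(10_000, 25_000, 100_000))
    h3k, motifs, blacklist = synth_tracks(truth, seed=11)
    return {
        "config": cfg,
        "mats": mats,
        "truth": truth,
        "h3k27ac": h3k,
        "motifs": motifs,
        "blacklist": blacklist,
        "m10": balance_sqrt_vc(mats[10_000]),
        "m100": balance_sqrt_vc(mats[100_000]),
    }


def dense_to_matrix(dense, resolution=10_000, uvp=None, chrom="chrT"):
    """Build a ContactMatrix from a full symmetric dense array (one chromosome)."""
    dense = np.asarray(dense, dtype=float)
    n = dense.shape[0]
    layout = GenomeLayout((chrom,), (n * resolution,))
    bins = BinIndex(layout, resolution)
    counts = sp.csr_matrix(np.triu(dense))
    total = int(counts.sum())
    return ContactMatrix(bins, counts, uvp=total if uvp is None else uvp)


@pytest.fixture
def toy3x3():
    """The 3x3 worked example used for virtual 4C arithmetic."""
    return dense_to_matrix([[0, 2, 4], [2, 6, 2], [4, 2, 0]], uvp=8)
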