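import numpy as np
import pytest

from skimbarcode.seq_io import Alignment, SequenceRecord, TaxonTable
from skimbarcode.synthetic_data import SimConfig, simulate


@pytest.fixture(scope="session")
def sim_small():
    """A small but fully featured simulated dataset (4 kb, default design)."""
    return simulate(SimConfig(seed=11, seq_length=4000))


@pytest.fixture(scope="session")
def sim_default():
    """The default-condition simulated dataset (12 kb, 16/10/6 design)."""
    return simulate(SimConfig(seed=23))


@pytest.fixture
def toy_taxa():
    """2 species; the second species split into two varieties (3+2+2)."""
    return TaxonTable(
        {
            "a1": ("sppA", "", "p1"),
            "a2": ("sppA", "", "p1"),
            "a3": ("sppA", "", "p2"),
            "b1": ("sppB", "v1", "p3"),
            "b2": ("sppB", "v1", "p3"),
            "c1": ("sppB", "v2", "p4"),
            "c2": ("sppB", "v2", "p4"),
        }
    )


def random_alignment(rng: np.random.Generator, n_seqs: int, n_cols: int,
                     gap_frac: float = 0.05, n_frac: float = 0.02) -> Alignment:
    """Random alignment over {A,C,G,T,N,-} with scattered gaps and Ns."""
    alphabet = np.array(list("ACGT"))
    mat = alphabet[rng.integers(0, 4, size=(n_seqs, n_cols))]
    mask = rng.random((n_seqs, n_cols))
    mat[mask < gap_frac] = "-"
    mat[(mask >= gap_frac) & (mask < gap_frac + n_frac)] = "N"
    # keep at least one base per column so no all-gap columns get stripped
    for c in range(n_cols):
        if (mat[:, c] == "-").all():
            mat[rng.integers(0, n_seqs), c] = "A"
    return Alignment(
        [SequenceRecord(f"s{i}", "".join(mat[i])) for i in range(n_seqs)]
    )
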