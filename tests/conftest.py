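import numpy as np
import pytest

from mhc2lig.data_io import BindingTable, ProteinRecord, ResidueFeatureTrack
from mhc2lig.synthetic_data import SyntheticConfig, generate_dataset


@pytest.fixture
def toy_protein():
    return ProteinRecord("prot1", "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ")


@pytest.fixture
def toy_track(toy_protein):
    n = len(toy_protein)
    rng = np.random.default_rng(42)
    comp = rng.dirichlet([2.0, 2.0, 2.0], size=n)
    nglyc = np.zeros(n, dtype=bool)
    oglyc = np.zeros(n, dtype=bool)
    nglyc[5] = True
    oglyc[20] = True
    return ResidueFeatureTrack(
        protein_id="prot1",
        rsa=rng.random(n),
        p_helix=comp[:, 0],
        p_strand=comp[:, 1],
        p_coil=comp[:, 2],
        nglyc=nglyc,
        oglyc=oglyc,
    )


@pytest.fixture
def toy_binding(toy_protein):
    """Binding scores for every 15-mer window of the toy protein."""
    rng = np.random.default_rng(7)
    length = 15
    n_windows = len(toy_protein) - length + 1
    scores = {}
    for start in range(n_windows):
        scores[("prot1", start, length, "DRB1*0401")] = float(
            rng.uniform(0.05, 0.95))
    return BindingTable(scores)


@pytest.fixture(scope="session")
def small_dataset():
    """Small synthetic dataset with planted exposure and binding signal."""
    config = SyntheticConfig(
        n_proteins=40,
        protein_length=(60, 90),
        delta_rsa=0.10,
        ligand_binding_boost=0.15,
        background_size=5_000,
        seed=11,
    )
    return generate_dataset(config)


@pytest.fixture(scope="session")
def null_dataset():
    """Synthetic dataset with no planted structural signal."""
    config = SyntheticConfig(
        n_proteins=40,
        protein_length=(60, 90),
        ligand_binding_boost=0.15,
        background_size=5_000,
        seed=13,
    )
    return generate_dataset(config)
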