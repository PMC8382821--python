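import numpy as np
import pytest

from azamine.io_formats import ProteinRecord
from azamine.synthetic import SyntheticConfig, generate_dataset

AA = "ACDEFGHIKLMNPQRSTVWY"


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA), size=length))


@pytest.fixture(scope="session")
def small_dataset():
    """12 genomes: 6 positives (both orders, both phosphatase classes,
    3 with planted motifs), 6 decoys of all three kinds."""
    config = SyntheticConfig(
        rng_seed=11,
        n_genomes=12,
        n_planted_3gc=6,
        motif_plants=3,
        decoy_spec={"two_gene": 2, "scattered": 2, "none": 2},
    )
    return generate_dataset(config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_records(rng, n, length=60):
    return [
        ProteinRecord(protein_id=f"p{i:03d}",
                      sequence=random_protein(rng, length),
                      organism=f"Genus{i % 3} species x")
        for i in range(n)
    ]
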