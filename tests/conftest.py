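import numpy as np
import pytest

from pepcsn import PeptideRecord, SyntheticSpec, generate_benchmark, generate_families

AA = "ACDEFGHIKLMNPQRSTVWY"


def random_peptides(n, length, seed, prefix="p"):
    rng = np.random.default_rng(seed)
    return [
        PeptideRecord(f"{prefix}{i}", "".join(rng.choice(list(AA), size=length)))
        for i in range(n)
    ]


@pytest.fixture(scope="session")
def synthetic_dataset():
    """Default family-structured synthetic set with family labels."""
    return generate_families(SyntheticSpec())


@pytest.fixture(scope="session")
def synthetic_benchmark(synthetic_dataset):
    records, _ = synthetic_dataset
    return generate_benchmark(records, rng_seed=2024)
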