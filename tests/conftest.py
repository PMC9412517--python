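import numpy as np
import pytest

from rodnilmf import (
    DnilmfConfig,
    KGETrainConfig,
    SyntheticSpec,
    generate_dti_network,
    generate_kg,
    init_embeddings,
)


@pytest.fixture(scope="session")
def small_network():
    """A compact planted network shared by read-only tests."""
    spec = SyntheticSpec(n_drugs=30, n_targets=25, latent_rank=3,
                         interaction_density=0.1, seed=7)
    Y, Sd, St, truth = generate_dti_network(spec)
    return {"spec": spec, "Y": Y, "drug_sim": Sd, "target_sim": St, "truth": truth}


@pytest.fixture(scope="session")
def small_kg(small_network):
    spec = small_network["spec"]
    return generate_kg(spec, small_network["Y"])


@pytest.fixture
def tiny_embedding():
    cfg = KGETrainConfig(dim=4, seed=11)
    return init_embeddings([f"e{i}" for i in range(6)], ["r0", "r1", "r2"], cfg), cfg
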