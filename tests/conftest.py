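import numpy as np
import pytest

from epimil.alleles import AlleleSpec
from epimil.model import ModelConfig, PresentationModel
from epimil.seqcore import AA_ALPHABET


@pytest.fixture(scope="session")
def tiny_config():
    return ModelConfig(n_blocks=2, n_heads=2, d_model=32)


@pytest.fixture(scope="session")
def tiny_model(tiny_config):
    return PresentationModel(tiny_config, seed=0)


@pytest.fixture(scope="session")
def synthetic_alleles():
    """Five synthetic alleles with distinct random 34-AA pseudo-sequences."""
    rng = np.random.default_rng(42)
    out = {}
    for i in range(5):
        pseudo = "".join(AA_ALPHABET[j] for j in rng.integers(0, 20, 34))
        out[f"SYN-{i:03d}"] = AlleleSpec.from_pseudo(f"SYN-{i:03d}", pseudo)
    return out
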