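import numpy as np
import pytest

from scvar.config import AnalysisConfig
from scvar.synthetic_fixtures import make_synthetic_chain, make_variant_pair


@pytest.fixture
def short_config():
    """Config with the chain-length gate lowered for small fixtures."""
    return AnalysisConfig(min_length_aa=10)


@pytest.fixture(scope="session")
def chain40():
    model, truth = make_synthetic_chain(40, seed=1)
    return model, truth


def make_chain_pair(n_res: int, change_fraction: float, seed: int):
    """Native chain A plus a variant renamed to chain B of the same crystal,
    with the ground-truth change labels re-keyed to chain A."""
    model, _ = make_synthetic_chain(n_res, seed=seed)
    variant, truth = make_variant_pair(model, change_fraction, seed=seed + 1000)
    variant.pdb_id = model.pdb_id
    variant.chains["B"] = variant.chains.pop("A")
    for residue in variant.chains["B"]:
        residue.chain_id = "B"
    labels = {key: flag for key, flag in truth.changed.items()}
    return model, variant, labels


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20160912)
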