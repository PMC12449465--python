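import numpy as np
import pytest

from ethnirisk import (
    ANCESTRIES,
    DEFAULT_PGS_PARAMS,
    AncestryProfile,
    PgsModel,
)
from ethnirisk.synthetic import make_toy_config, make_toy_pgs_model


@pytest.fixture(scope="session")
def toy_model() -> PgsModel:
    """10-SNP random panel with analytically exact per-ancestry moments."""
    return make_toy_pgs_model(n_snps=10, seed=1)


@pytest.fixture(scope="session")
def table2_model(toy_model) -> PgsModel:
    """Toy panel carrying the published breast 309-SNP standardisation
    parameters (used where tests check against the published mu/sd/alpha)."""
    return PgsModel(
        name="BC-309",
        snps=toy_model.snps,
        params_by_ancestry={a: DEFAULT_PGS_PARAMS["BC-309"][a] for a in ANCESTRIES},
    )


@pytest.fixture(scope="session")
def half_profile() -> AncestryProfile:
    return AncestryProfile({"European": 0.5, "African": 0.5})


@pytest.fixture(scope="session")
def toy_config():
    return make_toy_config(seed=0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
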