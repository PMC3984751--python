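import numpy as np
import pytest

from epistab import featexp, simgen
from epistab.genio import GenotypeMatrix, PhenotypeVector


@pytest.fixture
def rng():
    return np.random.default_rng(20140301)


@pytest.fixture
def tiny_genotypes(rng) -> GenotypeMatrix:
    """60 samples x 6 independent SNPs, complete calls."""
    vals = rng.binomial(2, 0.3, size=(60, 6)).astype(float)
    return GenotypeMatrix(vals, [f"rs{i}" for i in range(6)], [f"s{i}" for i in range(60)])


@pytest.fixture
def main_effect_dataset(rng):
    """n=400, m=8 independent SNPs with one strong main effect (OR 3)."""
    spec = simgen.BlockLDSpec.scaled(8, within_block_rho=0.0)
    G = simgen.simulate_genotypes(spec, 400, seed=11)
    eta = -0.5 + np.log(3.0) * G.values[:, 2]
    y = np.random.default_rng(12).binomial(1, 1 / (1 + np.exp(-eta)))
    F = featexp.standardize(featexp.expand_interactions(G))
    return F, PhenotypeVector(y), 2  # causal main-effect column
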