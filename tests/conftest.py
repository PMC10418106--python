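import numpy as np
import pytest

from dispersalnet.containers import GenotypeMatrix, LocationTable
from dispersalnet.network import ModelSpec, build_model


@pytest.fixture(scope="session")
def toy_weights():
    """A small 4-sample, 40-SNP model with randomized (non-zero) biases.

    Biases are jittered away from zero so that no pre-activation sits exactly
    on the ReLU kink, which would make finite-difference gradient checks
    ill-defined.
    """
    spec = ModelSpec(
        m_snps=40, n_samples=4, filters_per_block=(6,), pair_dense_units=8, seed=12345
    )
    ws = build_model(spec)
    rng = np.random.default_rng(99)
    for name, p in ws.params.items():
        if name.endswith("_b") and p.ndim:
            ws.params[name] = rng.normal(0.0, 0.1, size=p.shape)
    return ws


@pytest.fixture
def toy_dataset():
    """Deterministic 40-SNP, 4-sample genotype matrix + locations."""
    rng = np.random.default_rng(7)
    vals = rng.integers(0, 3, size=(40, 4)).astype(np.int16)
    # ensure rows segregate
    vals[vals.max(axis=1) == vals.min(axis=1), 0] += 1
    G = GenotypeMatrix(values=np.clip(vals, 0, 2), positions=np.arange(1.0, 41.0))
    L = LocationTable(coords=rng.uniform(0, 10, size=(4, 2)))
    return G, L


@pytest.fixture(scope="session")
def quick_sim():
    """One small finished simulation shared across tests (8x8 habitat)."""
    from dispersalnet.simulate import SimParams, run_simulation

    params = SimParams(habitat_width=8, sigma_f=0.8, n_generations=25, seed=42)
    return run_simulation(params, sample_n=20, draws=2, m_snps=100)
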