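import numpy as np
import pytest

from htrscan import simulate


@pytest.fixture(scope="session")
def small_panel():
    """Two species at 12% divergence, two strains each, two planted HTRs."""
    cfg = simulate.SimulationConfig(
        seed=1,
        genome_length=150_000,
        n_strains_per_species=2,
        background_divergence=0.12,
        theta=0.002,
        te_density=0.05,
        htr_specs=(
            simulate.HTRSpec(20_000, 0.998, (0, 1), te_at_edges=True),
            simulate.HTRSpec(10_000, 0.995, (0, 1), te_at_edges=False),
        ),
    )
    assemblies, annotations, truth = simulate.simulate_panel(cfg)
    return cfg, assemblies, annotations, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
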