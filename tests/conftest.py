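import numpy as np
import pytest

import enrichrank as er


@pytest.fixture
def tiny_data():
    """4 genes x 6 samples (3 control, 3 case); gene g3 strongly shifted."""
    rng = np.random.default_rng(11)
    values = rng.normal(8.0, 1.0, size=(4, 6))
    values[2, 3:] += 5.0
    return er.ExpressionDataset(
        values=values,
        gene_ids=["g1", "g2", "g3", "g4"],
        sample_ids=["c1", "c2", "c3", "t1", "t2", "t3"],
        groups=np.array([0, 0, 0, 1, 1, 1]),
    )


@pytest.fixture(scope="session")
def sim_small():
    """Small simulated study shared by fast tests (one spiked set)."""
    spec = er.SimulationSpec(
        n_genes=400,
        n_samples_per_group=5,
        n_sets=10,
        set_size=20,
        n_spiked_sets=1,
        effect_size=2.5,
        noise_sd=1.0,
        seed=5,
    )
    return er.simulate(spec)


@pytest.fixture(scope="session")
def sim_bench():
    """The benchmark study conditions: 2000 genes, 20 sets of 25, one spiked
    set with a 2-sd shift, 6 + 6 samples."""
    spec = er.SimulationSpec(
        n_genes=2000,
        n_samples_per_group=6,
        n_sets=20,
        set_size=25,
        n_spiked_sets=1,
        effect_size=2.0,
        noise_sd=1.0,
        network_consistency=1.0,
        seed=42,
    )
    return er.simulate(spec)
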