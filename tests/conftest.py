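import numpy as np
import pytest

import dynbrain as db


@pytest.fixture(scope="session")
def toy_series() -> db.RoiTimeSeries:
    """Small deterministic 8-region, 30-volume series."""
    return db.generate_subject(db.SyntheticSpec(m=8, T=30, seed=1))


@pytest.fixture(scope="session")
def diffusion_truth():
    """5-node graph-diffusion snapshots with exact closed-form evaluator."""
    return db.generate_dynamics_truth(m=5, n_obs=10, seed=42)


@pytest.fixture(scope="session")
def fitted_diffusion_model(diffusion_truth):
    seq, _ = diffusion_truth
    coupling = db.build_coupling_graph(seq, density=0.5)
    cfg = db.NdcnConfig(ode_solver="rk4", step_size=0.25, epochs=300,
                        seed=7, hidden_dim=16)
    return db.fit(seq, coupling, cfg)


@pytest.fixture
def symmetric_matrix():
    def make(m: int, seed: int = 0) -> np.ndarray:
        rng = np.random.default_rng(seed)
        x = rng.uniform(-0.9, 0.9, (m, m))
        x = (x + x.T) / 2
        np.fill_diagonal(x, 1.0)
        return x

    return make
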