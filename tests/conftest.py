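import numpy as np
import pytest

import actent as ae


@pytest.fixture(scope="session")
def driven_ou_ensemble():
    """Nonreciprocal 2-mode OU ensemble (k=1, alpha=1, D=I): closed-form
    entropy rate 2*alpha^2/k = 2.  Shared across estimator tests."""
    spec = ae.LangevinSpec(
        ae.nonreciprocal_drift(1.0, 1.0),
        np.eye(2),
        dt=0.005,
        n_steps=100_000,
        n_trajectories=20,
        seed=3,
    )
    return ae.simulate_mode_dynamics(spec)


@pytest.fixture(scope="session")
def driven_entropy_series(driven_ou_ensemble):
    fld = ae.phase_space_velocity_field(driven_ou_ensemble)
    D = ae.DiffusionModel(np.eye(2))
    return [ae.entropy_production(m, fld, D) for m in driven_ou_ensemble]


@pytest.fixture(scope="session")
def equilibrium_ou_ensemble():
    spec = ae.LangevinSpec(
        -np.eye(2), np.eye(2), dt=0.005, n_steps=20_000, n_trajectories=20, seed=5
    )
    return ae.simulate_mode_dynamics(spec)
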