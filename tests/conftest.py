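import numpy as np
import pytest

from cohesim import ParticleState, SimParams


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_params():
    """Five sparse particles with both torques on."""
    return SimParams(N=5, Phi=0.05, T0=3.0, R=2.0, seed=1)


def random_state(params: SimParams, rng: np.random.Generator) -> ParticleState:
    n = params.N
    return ParticleState(
        rng.uniform(0, params.L, (n, 2)),
        rng.uniform(-np.pi, np.pi, n),
        np.zeros((n, 2), dtype=np.int64),
    )


def brute_force_pairs(pos: np.ndarray, cutoff: float, L: float):
    """O(N^2) minimum-image pair scan; the neighbor-search oracle."""
    n = len(pos)
    out = set()
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = pos[i] - pos[j]
            d = d - L * np.round(d / L)
            if np.hypot(d[0], d[1]) < cutoff:
                out.add((i, j))
    return out


def brute_force_torques(state: ParticleState, params: SimParams) -> np.ndarray:
    """Direct double-loop evaluation of the total interaction torque."""
    from cohesim import alignment_torque, cohesion_torque

    n = state.N
    L = params.L
    torques = np.zeros(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = state.pos[i] - state.pos[j]
            d = d - L * np.round(d / L)
            r = np.hypot(d[0], d[1])
            torques[i] += alignment_torque(
                state.phi[i], state.phi[j], r, params.T_A, params.R_sigma)
            torques[i] += cohesion_torque(state.u[i], d, params.T_C, params.R_sigma)
    return torques
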