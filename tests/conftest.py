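import numpy as np
import pytest

from velodirect import SimConfig, make_directional_benchmark, simulate_population


@pytest.fixture(scope="session")
def benchmark_ds():
    """Directional benchmark (4 classes, high separation) as a CountDataset."""
    return make_directional_benchmark(n_cells=600, d=4, separation=8.0, seed=11).to_count_dataset()


@pytest.fixture(scope="session")
def sim_ds():
    """A small clustered kinetic simulation with Poisson noise."""
    return simulate_population(SimConfig(n_cells=300, n_genes=120, n_clusters=3, seed=5))


def rk4_constant_alpha(alpha, beta, gamma, u0, s0, t_span, n_steps):
    """Independent numeric oracle: fixed-step RK4 on one constant-alpha phase.

    All parameters may be arrays (vectorized over parameter sets); returns
    the state (u, s) after integrating for ``t_span`` time units.
    """
    alpha, beta, gamma = np.broadcast_arrays(
        np.asarray(alpha, float), np.asarray(beta, float), np.asarray(gamma, float))
    u = np.broadcast_to(np.asarray(u0, float), alpha.shape).copy()
    s = np.broadcast_to(np.asarray(s0, float), alpha.shape).copy()
    h = np.asarray(t_span, float) / n_steps

    def rhs(u, s):
        return alpha - beta * u, beta * u - gamma * s

    for _ in range(n_steps):
        k1u, k1s = rhs(u, s)
        k2u, k2s = rhs(u + h / 2 * k1u, s + h / 2 * k1s)
        k3u, k3s = rhs(u + h / 2 * k2u, s + h / 2 * k2s)
        k4u, k4s = rhs(u + h * k3u, s + h * k3s)
        u = u + h / 6 * (k1u + 2 * k2u + 2 * k3u + k4u)
        s = s + h / 6 * (k1s + 2 * k2s + 2 * k3s + k4s)
    return u, s


def rk4_solve(params, t, n_steps_per_phase=2000):
    """RK4 oracle for the switched kinetics: integrate the induction phase to
    min(t, t_switch), then the repression phase (alpha = 0) for the rest."""
    t_on = min(t, params.t_switch)
    u, s = rk4_constant_alpha(params.alpha, params.beta, params.gamma,
                              params.u0, params.s0, t_on, n_steps_per_phase)
    if t > params.t_switch:
        u, s = rk4_constant_alpha(0.0, params.beta, params.gamma,
                                  u, s, t - params.t_switch, n_steps_per_phase)
    return float(u), float(s)
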