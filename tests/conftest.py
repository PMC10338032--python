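import numpy as np
import pytest
from scipy import integrate, interpolate, stats

from chromicelle.engine import SimulationConfig, SystemState
from chromicelle.engine.config import TYPE_A, TYPE_B, TYPE_P


def boltzmann_bond_length_ks(r, k_spring, temperature=1.0):
    """KS test of bond-length samples against the Boltzmann marginal
    P(r) dr ~ r^2 exp(-beta k (r - 1)^2) dr of a harmonic dimer."""
    grid = np.linspace(0.5, 1.5, 4001)
    pdf = grid**2 * np.exp(-k_spring / temperature * (grid - 1.0) ** 2)
    cdf = integrate.cumulative_trapezoid(pdf, grid, initial=0.0)
    cdf /= cdf[-1]
    ref = interpolate.interp1d(
        grid, cdf, bounds_error=False, fill_value=(0.0, 1.0)
    )
    return stats.kstest(r, ref)


def make_state(positions, types, n_chain, partner=None, seed=0):
    positions = np.asarray(positions, dtype=np.float64)
    types = np.asarray(types, dtype=np.int8)
    if partner is None:
        partner = np.full(len(positions), -1, np.int32)
    return SystemState(
        positions=positions,
        velocities=np.zeros_like(positions),
        types=types,
        n_chain=n_chain,
        partner=np.asarray(partner, dtype=np.int32),
        rng=np.random.default_rng(seed),
    )


def random_mixed_state(n_chain=40, n_protein=20, seed=0, R_c=12.0, bond_some=False):
    """A compact random state with all bead species and optional bonds."""
    rng = np.random.default_rng(seed)
    config = SimulationConfig(
        n_blocks=2,
        N_A=n_chain // 4,
        N_B=n_chain // 4,
        N_p=n_protein,
        R_c=R_c,
        K=5.0,
        seed=seed,
    )
    # chain as a mildly wiggly walk, proteins sprinkled nearby
    pos = np.zeros((config.n_total, 3))
    cur = np.zeros(3)
    for i in range(1, n_chain):
        while True:
            step = rng.standard_normal(3)
            step /= np.linalg.norm(step)
            nxt = cur + step
            if np.linalg.norm(nxt) > R_c - 2.0:
                continue
            if np.any(np.linalg.norm(pos[: i - 1] - nxt, axis=1) < 0.9):
                continue
            break
        cur = nxt
        pos[i] = cur
    for i in range(n_chain, config.n_total):
        while True:
            # drop proteins in shells around random chain beads so some
            # land inside the bonding capture radius
            anchor = pos[rng.integers(0, n_chain)]
            direction = rng.standard_normal(3)
            direction /= np.linalg.norm(direction)
            p = anchor + direction * rng.uniform(0.95, 2.5)
            if np.linalg.norm(p) < R_c - 2.0 and np.all(
                np.linalg.norm(pos[:i] - p, axis=1) > 0.8
            ):
                pos[i] = p
                break
    state = make_state(pos, config.bead_types(), n_chain, seed=seed)
    if bond_some:
        from chromicelle.engine import update_dynamic_bonds

        update_dynamic_bonds(state, config)
    return state, config


@pytest.fixture(scope="session")
def short_desk_run():
    """A short desk-scale bonded run shared across analysis tests."""
    from chromicelle.engine import run_simulation
    from chromicelle.fixtures import preset

    config = preset("desk_small")
    config.K = 5.0
    config.n_steps = 20_000
    config.dump_interval = 2000
    config.seed = 7
    return run_simulation(config)


@pytest.fixture(scope="session")
def diffusion_msd_slope():
    """Long-time MSD slope of non-interacting beads (Einstein: 60 a^2/tau).

    Time- and ensemble-averaged over 400 free beads and 2000 tau, with all
    fitted lags far beyond the 10 tau damping time.
    """
    from chromicelle.engine import run_simulation

    cfg = SimulationConfig(
        n_blocks=1,
        N_A=1,
        N_B=1,
        N_p=400,
        R_c=1500.0,
        eps_matrix={k: 0.0 for k in ("AA", "AB", "BB", "AP", "BP", "PP")},
        K=0.0,
        n_steps=200_000,
        dump_interval=2000,
        log_interval=100_000,
        seed=12,
    )
    rng = np.random.default_rng(12)
    pos = np.zeros((cfg.n_total, 3))
    pos[1] = [1.0, 0, 0]
    pos[2:] = rng.standard_normal((cfg.N_p, 3)) * 5.0
    state = make_state(pos, cfg.bead_types(), 2, seed=12)
    state.velocities = rng.standard_normal(pos.shape)
    state.rng = rng
    res = run_simulation(cfg, state=state)
    frames = res.trajectory.positions[:, 2:, :]
    dt_frame = (res.trajectory.steps[1] - res.trajectory.steps[0]) * cfg.dt
    lags = np.array([10, 20, 30, 40, 50])
    msd = []
    for lag in lags:
        d = frames[lag:] - frames[:-lag]
        msd.append(np.mean(np.sum(d * d, axis=2)))
    return float(np.polyfit(lags * dt_frame, msd, 1)[0])


@pytest.fixture(scope="session")
def dimer_bond_length_samples():
    """10^5 decorrelated bond-length samples of an isolated harmonic dimer
    (k = 100, T = 1) plus the stiffness used, for Boltzmann checks."""
    from chromicelle.engine import run_simulation
    from chromicelle.fixtures import preset

    cfg = preset("dimer_test")
    cfg.n_steps = 40_000_000
    cfg.dump_interval = 400  # 2 tau between samples: decorrelated
    cfg.log_interval = 10_000_000
    cfg.seed = 4
    state = make_state([[0, 0, 0], [1.0, 0, 0]], [TYPE_A, TYPE_B], 2, seed=4)
    state.velocities = np.random.default_rng(4).standard_normal((2, 3))
    res = run_simulation(cfg, state=state)
    d = res.trajectory.positions[:, 0, :] - res.trajectory.positions[:, 1, :]
    r = np.linalg.norm(d, axis=1)
    return r[25:], cfg.k_spring  # drop the brief equilibration transient


@pytest.fixture(scope="session")
def desk_bonding_sweep():
    """The bonding-strength sweep at desk scale: K in {0, 2, 5, 10}, three
    seeds each.  Runs are shortened to 1.5x10^5 steps, well past the
    steady state of this system size (reached by ~10^5 steps), with
    statistics over the final quarter of frames."""
    from chromicelle.fixtures import preset
    from chromicelle.sweep import sweep_K

    config = preset("desk_small")
    config.n_steps = 150_000
    return sweep_K(
        config, K_values=[0.0, 2.0, 5.0, 10.0], seeds=[0, 1, 2],
        min_core_size=5,
    )
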