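"""Langevin dynamics driver: force evaluation, integration, dynamic-bond
updates, full production runs with logging, dumping and checkpointing.

Integration is BAOAB velocity-Verlet Langevin with m = 1 and friction
gamma = 1/damping, which reproduces the Einstein long-time diffusivity
D = k_B T * damping / m.  All randomness flows from a single
``numpy.random.Generator`` whose state is checkpointed, so runs are
bit-reproducible per seed and restartable.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import kernels
from .config import SimulationConfig
from .state import SystemState, Trajectory
from .kernels import STATUS_OK, STATUS_OUTSIDE, STATUS_OVERFLOW, STATUS_UNSTABLE

#: Steps per block of pre-generated Gaussian kicks.  Checkpoints are taken
#: at multiples of this, which makes restarts bit-identical to an
#: uninterrupted run.
CHUNK = 2000

CHECKPOINT_VERSION = 1


class InstabilityError(RuntimeError):
    """A bead moved more than 0.5 a in one step; reduce dt."""


class ConfinementError(RuntimeError):
    """A bead left the confinement sphere (corrupted state)."""


class _Workspace:
    """Pair tables, neighbor-list buffers and the persistent force array."""

    def __init__(self, state: SystemState, config: SimulationConfig):
        self.config = config
        eps, cut = config.pair_tables()
        self.eps_tab = np.ascontiguousarray(eps)
        self.cut2_tab = np.ascontiguousarray(cut**2)
        self.r_list = float(np.max(cut)) + config.skin
        self.r_list2 = self.r_list**2
        self.box_R = config.R_c + 1.0
        # cells never smaller than the list cutoff, and never so numerous
        # that the grid dwarfs the bead count (bigger cells stay correct,
        # they only admit more candidates)
        n_total = state.n_total
        cap = max(4, int(np.ceil((2.0 * n_total) ** (1.0 / 3.0))))
        self.ncell = min(max(1, int(2.0 * self.box_R / self.r_list)), cap, 64)
        self.skin = config.skin
        n = state.n_total
        self._alloc(max(96 * n, 4096), max(16 * n, 1024))
        self.meta = np.zeros(4, np.int64)
        self.pos_ref = np.empty((n, 3))
        self.f = np.zeros((n, 3))
        self.rebuild(state)
        self.refresh_forces(state)

    def _alloc(self, cap: int, ap_cap: int) -> None:
        self.pair_i = np.empty(cap, np.int32)
        self.pair_j = np.empty(cap, np.int32)
        self.pair_eps4 = np.empty(cap)
        self.pair_cut2 = np.empty(cap)
        self.ap_i = np.empty(ap_cap, np.int32)
        self.ap_j = np.empty(ap_cap, np.int32)

    def rebuild(self, state: SystemState) -> None:
        while True:
            npair, nap = kernels.build_pairs(
                state.positions,
                state.types,
                state.n_chain,
                self.r_list2,
                self.box_R,
                self.ncell,
                self.eps_tab,
                self.cut2_tab,
                self.pair_i,
                self.pair_j,
                self.pair_eps4,
                self.pair_cut2,
                self.ap_i,
                self.ap_j,
            )
            if npair >= 0:
                break
            self._alloc(2 * len(self.pair_i), 2 * len(self.ap_i))
        self.meta[0] = npair
        self.meta[1] = nap
        self.pos_ref[:] = state.positions

    def refresh_forces(self, state: SystemState) -> None:
        c = self.config
        status = kernels.compute_forces(
            state.positions,
            self.f,
            state.partner,
            state.n_chain,
            self.pair_i,
            self.pair_j,
            self.pair_eps4,
            self.pair_cut2,
            self.meta[0],
            self.eps_tab,
            self.cut2_tab,
            state.types,
            c.k_spring,
            c.K,
            c.r0,
            c.r_break**2,
            c.R_c,
            c.eps_confine,
            np.zeros(1, np.int64),
        )
        _raise_on_status(status)

    def energies(self, state: SystemState):
        c = self.config
        return kernels.energy_report(
            state.positions,
            state.partner,
            state.n_chain,
            self.pair_i,
            self.pair_j,
            self.pair_eps4,
            self.pair_cut2,
            self.meta[0],
            self.eps_tab,
            self.cut2_tab,
            state.types,
            c.k_spring,
            c.K,
            c.r0,
            c.r_break**2,
            c.R_c,
            c.eps_confine,
        )

    def sweep_bonds(self, state: SystemState) -> int:
        c = self.config
        return kernels.bond_sweep(
            state.positions,
            state.partner,
            self.ap_i,
            self.ap_j,
            self.meta[1],
            c.r_bond**2,
            c.r_break**2,
        )

    def advance(self, state: SystemState, normals: np.ndarray) -> None:
        c = self.config
        c1 = math.exp(-c.dt / c.damping)
        c2 = math.sqrt((1.0 - c1 * c1) * c.temperature)
        status = kernels.advance_segment(
            state.positions,
            state.velocities,
            self.f,
            state.types,
            state.partner,
            state.n_chain,
            self.eps_tab,
            self.cut2_tab,
            c.k_spring,
            c.K,
            c.r0,
            c.r_break**2,
            c.R_c,
            c.eps_confine,
            c.dt,
            c1,
            c2,
            normals,
            self.pair_i,
            self.pair_j,
            self.pair_eps4,
            self.pair_cut2,
            self.ap_i,
            self.ap_j,
            self.meta,
            self.pos_ref,
            self.r_list2,
            self.box_R,
            self.ncell,
            self.skin,
        )
        if status == STATUS_OVERFLOW:
            # capacity is sized far beyond physical neighbor counts, so
            # this indicates a corrupted state rather than a full list
            raise RuntimeError("neighbor-list capacity exceeded mid-run")
        _raise_on_status(status)
        state.n_capped = int(self.meta[2])


def _raise_on_status(status: int) -> None:
    if status == STATUS_OK:
        return
    if status == STATUS_OUTSIDE:
        raise ConfinementError("bead left the confinement sphere")
    if status == STATUS_UNSTABLE:
        raise InstabilityError(
            "per-step displacement exceeded 0.5 a; use a smaller dt"
        )
    raise RuntimeError(f"unknown kernel status {status}")


# ---------------------------------------------------------------------------
# public single-shot operations


def compute_forces(state: SystemState, config: SimulationConfig) -> np.ndarray:
    """Forces -grad U_total on every bead for the given state."""
    ws = _Workspace(state, config)
    return ws.f.copy()


def update_dynamic_bonds(state: SystemState, config: SimulationConfig) -> int:
    """One bond sweep (break over-stretched bonds, then form new ones
    subject to valence 1).  Mutates ``state.partner``; returns the number
    of changes."""
    ws = _Workspace(state, config)
    return ws.sweep_bonds(state)


def integrate_step(
    state: SystemState, config: SimulationConfig, n_steps: int = 1
) -> SystemState:
    """Advance ``n_steps`` Langevin steps in place (no bond updates,
    logging or dumping — the elementary integrator, mainly for tests)."""
    ws = _Workspace(state, config)
    normals = state.rng.standard_normal((n_steps, state.n_total, 3), dtype=np.float32)
    ws.advance(state, normals)
    state.step += n_steps
    return state


# ---------------------------------------------------------------------------
# production runs


@dataclass
class SimulationResult:
    config: SimulationConfig
    state: SystemState
    series: pd.DataFrame
    trajectory: Trajectory
    n_capped: int = 0
    manifest: dict = field(default_factory=dict)


def _chromatin_rg(state: SystemState) -> float:
    pos = state.positions[: state.n_chain]
    com = pos.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum((pos - com) ** 2, axis=1))))


def run_simulation(
    config: SimulationConfig,
    state: SystemState | None = None,
    checkpoint_path: str | Path | None = None,
    checkpoint_every: int | None = None,
    collect_frames: bool = True,
) -> SimulationResult:
    """Run ``config.n_steps`` of Langevin dynamics with dynamic bonding.

    The initial configuration is generated from ``config.seed`` unless a
    prepared ``state`` (e.g. from a checkpoint) is passed; a restarted run
    continues bit-identically to the uninterrupted one.  Bonding is
    disabled entirely when ``K = 0``.  On an integration failure a final
    checkpoint is written (when ``checkpoint_path`` is set) before the
    error propagates.
    """
    if state is None:
        from ..fixtures import generate_initial_configuration

        state = generate_initial_configuration(config)
    if checkpoint_every is None:
        checkpoint_every = 25 * CHUNK
    if checkpoint_every % CHUNK != 0:
        raise ValueError(f"checkpoint_every must be a multiple of {CHUNK}")
    if state.step % CHUNK != 0:
        raise ValueError(f"restart step must be a multiple of {CHUNK}")

    ws = _Workspace(state, config)
    bonding = config.K > 0.0
    n_steps = config.n_steps
    N = state.n_total

    log_rows = []
    frames_steps, frames_pos, frames_partner = [], [], []

    def log_now():
        us, ulj, uc, ub = ws.energies(state)
        log_rows.append(
            (
                state.step,
                us + ulj + uc + ub,
                us,
                ulj,
                uc,
                ub,
                _chromatin_rg(state),
                state.n_bonds,
            )
        )

    def dump_now():
        if frames_steps and frames_steps[-1] == state.step:
            return
        frames_steps.append(state.step)
        frames_pos.append(state.positions.copy())
        frames_partner.append(state.partner.copy())

    if state.step == 0:
        log_now()
        if collect_frames:
            dump_now()

    def boundaries(step):
        nxt = [((step // iv) + 1) * iv for iv in (
            config.bond_update_interval if bonding else n_steps,
            config.log_interval,
            config.dump_interval,
        )]
        chunk_end = ((step // CHUNK) + 1) * CHUNK
        return min(min(nxt), chunk_end, n_steps)

    normals = None
    chunk_start = -1
    try:
        while state.step < n_steps:
            chunk = state.step // CHUNK
            if chunk != chunk_start:
                chunk_len = min(CHUNK, n_steps - chunk * CHUNK)
                normals = state.rng.standard_normal((chunk_len, N, 3), dtype=np.float32)
                if chunk_start >= 0 or state.step > 0:
                    # align the neighbor-list schedule (and hence floating
                    # -point summation order) with chunk boundaries so a
                    # restarted run is bit-identical to an uninterrupted one
                    ws.rebuild(state)
                    ws.refresh_forces(state)
                chunk_start = chunk
            target = boundaries(state.step)
            off = state.step - chunk * CHUNK
            seg = normals[off : off + (target - state.step)]
            ws.advance(state, seg)
            state.step = target
            if bonding and state.step % config.bond_update_interval == 0:
                if ws.sweep_bonds(state) > 0:
                    ws.refresh_forces(state)
            if state.step % config.log_interval == 0 or state.step == n_steps:
                log_now()
            if collect_frames and (
                state.step % config.dump_interval == 0 or state.step == n_steps
            ):
                dump_now()
            if (
                checkpoint_path is not None
                and state.step % checkpoint_every == 0
            ):
                save_checkpoint(checkpoint_path, state, config)
    except (InstabilityError, ConfinementError):
        if checkpoint_path is not None:
            save_checkpoint(checkpoint_path, state, config)
        raise

    if checkpoint_path is not None:
        save_checkpoint(checkpoint_path, state, config)

    series = pd.DataFrame(
        log_rows,
        columns=[
            "step",
            "U_total",
            "U_stretch",
            "U_LJ",
            "U_confine",
            "U_bond",
            "Rg",
            "n_bonds",
        ],
    ).drop_duplicates(subset="step", keep="last")
    traj = Trajectory(
        steps=np.array(frames_steps, dtype=np.int64),
        positions=(
            np.stack(frames_pos) if frames_pos else np.empty((0, N, 3))
        ),
        types=state.types.copy(),
        partners=(
            np.stack(frames_partner)
            if frames_partner
            else np.empty((0, N), np.int32)
        ),
        n_chain=state.n_chain,
    )
    return SimulationResult(
        config=config,
        state=state,
        series=series,
        trajectory=traj,
        n_capped=state.n_capped,
    )


# ---------------------------------------------------------------------------
# checkpointing (versioned JSON: full state + generator state)


def save_checkpoint(
    path: str | Path, state: SystemState, config: SimulationConfig
) -> None:
    doc = {
        "version": CHECKPOINT_VERSION,
        "config": config.to_dict(),
        "step": state.step,
        "n_chain": state.n_chain,
        "n_capped": state.n_capped,
        "positions": state.positions.ravel().tolist(),
        "velocities": state.velocities.ravel().tolist(),
        "partner": state.partner.tolist(),
        "rng_state": state.rng.bit_generator.state,
    }
    Path(path).write_text(json.dumps(doc))


def load_checkpoint(path: str | Path) -> tuple[SimulationConfig, SystemState]:
    doc = json.loads(Path(path).read_text())
    if doc.get("version") != CHECKPOINT_VERSION:
        raise ValueError(f"unsupported checkpoint version {doc.get('version')}")
    config = SimulationConfig.from_dict(doc["config"])
    n = config.n_total
    rng = np.random.default_rng()
    rng.bit_generator.state = doc["rng_state"]
    state = SystemState(
        positions=np.array(doc["positions"]).reshape(n, 3),
        velocities=np.array(doc["velocities"]).reshape(n, 3),
        types=config.bead_types(),
        n_chain=doc["n_chain"],
        partner=np.array(doc["partner"], dtype=np.int32),
        step=doc["step"],
        rng=rng,
        n_capped=doc["n_capped"],
    )
    return config, state
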