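"""Deterministic generators: initial configurations, presets and
planted-cluster frames.

Everything here is reproducible from a seed, so the whole package is
testable without external data.  The ``paper_full`` preset is the
published-scale system (500 blocks of 100+100 beads, 50,000 protein
beads, chromatin volume fraction 1%, confinement radius 108 a, 10^7
steps); ``desk_small`` is its scaled-down analogue that preserves the
dimensionless ratios the theory cares about (volume fraction 0.01,
protein:active-bead ratio 1, N_A = N_B, identical interaction matrix and
bonding cutoffs).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .engine.config import SimulationConfig, TYPE_B
from .engine.state import SystemState, TrajectoryFrame
from .engine.dynamics import _Workspace

PRESET_NAMES = ("paper_full", "desk_small", "dimer_test", "planted_clusters")

_OVERLAP_FLOOR = 0.9  # minimum pair distance accepted during placement
_WALL_MARGIN = 1.2  # placement keeps beads this far inside the sphere


def preset(name: str):
    """Named configurations.

    ``paper_full`` and ``desk_small`` return production
    :class:`SimulationConfig` objects; ``dimer_test`` a two-bead harmonic
    dimer with all pair interactions switched off; ``planted_clusters``
    the default :class:`PlantedSpec` for analysis ground-truth frames.
    """
    if name == "paper_full":
        return SimulationConfig(
            n_blocks=500,
            N_A=100,
            N_B=100,
            N_p=50_000,
            phi=0.01,
            R_c=108.0,  # the published rounded value
            n_steps=10_000_000,
            dump_interval=100_000,
            log_interval=10_000,
            name="paper_full",
        )
    if name == "desk_small":
        return SimulationConfig(
            n_blocks=20,
            N_A=20,
            N_B=20,
            N_p=400,
            phi=0.01,
            n_steps=500_000,
            dump_interval=5000,
            log_interval=1000,
            name="desk_small",
        )
    if name == "dimer_test":
        return SimulationConfig(
            n_blocks=1,
            N_A=1,
            N_B=1,
            N_p=0,
            phi=0.01,
            R_c=50.0,
            eps_matrix={k: 0.0 for k in ("AA", "AB", "BB", "AP", "BP", "PP")},
            K=0.0,
            # resolve the stiff bond vibration and decorrelate samples
            # quickly: omega*dt = 0.1, friction time 0.5 tau
            dt=0.005,
            damping=0.5,
            n_steps=10_000,
            dump_interval=1000,
            log_interval=1000,
            name="dimer_test",
        )
    if name == "planted_clusters":
        return PlantedSpec()
    raise ValueError(f"unknown preset {name!r}; known: {PRESET_NAMES}")


# ---------------------------------------------------------------------------
# initial configurations


class _Grid:
    """Occupancy grid for overlap rejection during placement."""

    def __init__(self, cell: float = 1.0):
        self.cell = cell
        self.cells: dict[tuple, list] = {}
        self.points: list = []

    def _key(self, p):
        c = self.cell
        return (int(p[0] // c), int(p[1] // c), int(p[2] // c))

    def clear_of(self, p, floor2: float) -> bool:
        kx, ky, kz = self._key(p)
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    for q in self.cells.get((kx + dx, ky + dy, kz + dz), ()):
                        d = (
                            (p[0] - q[0]) ** 2
                            + (p[1] - q[1]) ** 2
                            + (p[2] - q[2]) ** 2
                        )
                        if d < floor2:
                            return False
        return True

    def add(self, p) -> None:
        self.cells.setdefault(self._key(p), []).append(p)
        self.points.append(p)


def _uniform_in_sphere(rng: np.random.Generator, radius: float) -> np.ndarray:
    direction = rng.standard_normal(3)
    direction /= np.linalg.norm(direction)
    return direction * radius * rng.random() ** (1.0 / 3.0)


def generate_initial_configuration(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    relax_steps: int = 1000,
    max_retries: int = 40,
) -> SystemState:
    """Chain grown as a constrained random walk inside the sphere, protein
    beads placed uniformly, both with a 0.9 a minimum-distance rejection,
    followed by ``relax_steps`` of displacement-capped steepest descent.

    Deterministic per seed; velocities are drawn from the Maxwell
    distribution after relaxation.  Raises if placement keeps failing
    (overly dense configuration).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n_chain = config.n_chromatin
    r_max = config.R_c - _WALL_MARGIN
    if r_max <= 1.0:
        raise ValueError("confinement sphere too small for placement")
    floor2 = _OVERLAP_FLOOR**2

    for _attempt in range(max_retries):
        grid = _Grid()
        ok = True
        cur = _uniform_in_sphere(rng, max(r_max - 2.0, 0.5))
        grid.add(tuple(cur))
        for _ in range(1, n_chain):
            placed = False
            for _try in range(200):
                step = rng.standard_normal(3)
                step /= np.linalg.norm(step)
                nxt = cur + step
                if nxt @ nxt > r_max**2:
                    continue
                if not grid.clear_of(nxt, floor2):
                    continue
                cur = nxt
                grid.add(tuple(cur))
                placed = True
                break
            if not placed:
                ok = False
                break
        if not ok:
            continue
        for _ in range(config.N_p):
            placed = False
            for _try in range(500):
                p = _uniform_in_sphere(rng, r_max)
                if grid.clear_of(p, floor2):
                    grid.add(tuple(p))
                    placed = True
                    break
            if not placed:
                ok = False
                break
        if ok:
            break
    else:
        raise RuntimeError(
            "placement failed repeatedly: configuration too dense"
        )

    positions = np.array(grid.points, dtype=np.float64)
    state = SystemState(
        positions=positions,
        velocities=np.zeros_like(positions),
        types=config.bead_types(),
        n_chain=n_chain,
        partner=np.full(config.n_total, -1, np.int32),
        rng=rng,
    )
    if relax_steps > 0:
        # coarse descent removes placement strain; a fine-stepped polish
        # settles the stiff chain springs without overshoot
        _relax(state, config, relax_steps, max_disp=0.02)
        _relax(state, config, relax_steps, max_disp=0.005)
    state.velocities = rng.standard_normal(positions.shape) * math.sqrt(
        config.temperature
    )
    return state


def _relax(
    state: SystemState,
    config: SimulationConfig,
    n_iter: int,
    max_disp: float = 0.02,
) -> None:
    """Displacement-capped steepest descent to remove placement strain."""
    ws = _Workspace(state, config)
    for _ in range(n_iter):
        fmax = float(np.abs(ws.f).max())
        if fmax < 1e-6:
            break
        scale = max_disp / max(fmax, 1.0)
        state.positions += np.clip(ws.f * scale, -max_disp, max_disp)
        ws.rebuild(state)
        ws.refresh_forces(state)


# ---------------------------------------------------------------------------
# planted clusters (analysis ground truth)


@dataclass
class PlantedSpec:
    """Blueprint for frames with known core counts and sizes.

    ``sizes`` lists the bead count of each inactive-bead blob; blobs are
    compact cubic-lattice balls with lattice constant ``spacing`` whose
    bounding spheres are separated by at least ``gap``.  Optional loose A
    and P beads are sprinkled far (> gap/2) from every blob.
    """

    sizes: tuple = (30, 30)
    gap: float = 10.0
    spacing: float = 1.0
    n_A: int = 0
    n_P: int = 0
    R_c: float | None = None
    seed: int = 0

    def __post_init__(self):
        self.sizes = tuple(int(s) for s in self.sizes)
        if any(s < 1 for s in self.sizes):
            raise ValueError("cluster sizes must be >= 1")
        if self.gap <= 0 or self.spacing <= 0:
            raise ValueError("gap and spacing must be positive")


def _blob_offsets(size: int, spacing: float) -> np.ndarray:
    """The ``size`` cubic-lattice sites closest to the origin."""
    half = int(math.ceil(size ** (1.0 / 3.0))) + 1
    axis = np.arange(-half, half + 1)
    grid = np.stack(np.meshgrid(axis, axis, axis, indexing="ij"), axis=-1)
    pts = grid.reshape(-1, 3).astype(np.float64) * spacing
    order = np.argsort(np.sum(pts**2, axis=1), kind="stable")
    return pts[order[:size]]


@dataclass
class PlantedTruth:
    sizes: tuple
    centers: np.ndarray
    member_slices: list = field(default_factory=list)


def make_planted_clusters(
    spec: PlantedSpec, rng: np.random.Generator | None = None
) -> tuple[TrajectoryFrame, PlantedTruth]:
    """Build one frame realizing ``spec``; returns it with ground truth.

    Raises if the blobs cannot be placed inside the sphere with the
    requested gaps (infeasible spec).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    blobs = [_blob_offsets(s, spec.spacing) for s in spec.sizes]
    blobs = [b - b.mean(axis=0) for b in blobs]  # centroid at the center
    radii = [
        float(np.max(np.linalg.norm(b, axis=1))) if len(b) > 1 else 0.0
        for b in blobs
    ]
    R = spec.R_c
    if R is None:
        # generous sphere: fits the blobs with room for the gaps
        R = (sum(2 * r + spec.gap for r in radii) + spec.gap) * 1.5 + 5.0

    centers = []
    for k, r_k in enumerate(radii):
        for _try in range(5000):
            c = _uniform_in_sphere(rng, max(R - r_k - 1.0, 0.1))
            if all(
                np.linalg.norm(c - centers[m]) >= radii[m] + r_k + spec.gap
                for m in range(k)
            ):
                centers.append(c)
                break
        else:
            raise ValueError(
                "infeasible planted spec: cannot place clusters with the "
                "requested gap inside the sphere"
            )
    centers = np.array(centers) if centers else np.empty((0, 3))

    parts = [c + b for c, b in zip(centers, blobs)]
    truth = PlantedTruth(sizes=spec.sizes, centers=centers)
    start = 0
    for s in spec.sizes:
        truth.member_slices.append(slice(start, start + s))
        start += s
    b_pos = (
        np.concatenate(parts) if parts else np.empty((0, 3))
    )

    def _far_point():
        for _try in range(5000):
            p = _uniform_in_sphere(rng, R - 1.0)
            if all(
                np.linalg.norm(p - centers[m]) >= radii[m] + spec.gap / 2.0
                for m in range(len(radii))
            ):
                return p
        raise ValueError("infeasible planted spec: no room for loose beads")

    a_pos = np.array([_far_point() for _ in range(spec.n_A)]).reshape(-1, 3)
    p_pos = np.array([_far_point() for _ in range(spec.n_P)]).reshape(-1, 3)

    positions = np.concatenate([b_pos, a_pos, p_pos])
    types = np.concatenate(
        [
            np.full(len(b_pos), TYPE_B, np.int8),
            np.zeros(len(a_pos), np.int8),
            np.full(len(p_pos), 2, np.int8),
        ]
    )
    frame = TrajectoryFrame(
        step=0,
        positions=positions,
        types=types,
        partner=np.full(len(positions), -1, np.int32),
    )
    return frame, truth
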