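"""System state, energy report and trajectory containers."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import SimulationConfig


@dataclass
class EnergyReport:
    """Potential-energy components (k_B T)."""

    U_stretch: float
    U_LJ: float
    U_confine: float
    U_bond: float

    @property
    def U_total(self) -> float:
        return self.U_stretch + self.U_LJ + self.U_confine + self.U_bond


@dataclass
class SystemState:
    """Positions, velocities, types and the dynamic-bond registry.

    ``partner[i]`` is the index of the bead dynamically bonded to bead i,
    or -1.  Valence 1 for both species: each index appears in at most one
    bond.  The chromatin chain is beads 0..n_chain-1 with implicit chain
    bonds (i, i+1).
    """

    positions: np.ndarray
    velocities: np.ndarray
    types: np.ndarray
    n_chain: int
    partner: np.ndarray
    step: int = 0
    rng: np.random.Generator = field(
        default_factory=lambda: np.random.default_rng(0)
    )
    n_capped: int = 0

    @property
    def n_total(self) -> int:
        return len(self.positions)

    @property
    def chain_bonds(self) -> np.ndarray:
        i = np.arange(self.n_chain - 1)
        return np.stack([i, i + 1], axis=1)

    @property
    def dynamic_bonds(self) -> np.ndarray:
        """(n_bonds, 2) array of (chromatin bead, protein bead) pairs."""
        i = np.nonzero(self.partner >= 0)[0]
        i = i[i < self.partner[i]]
        return np.stack([i, self.partner[i]], axis=1)

    @property
    def n_bonds(self) -> int:
        return int(np.count_nonzero(self.partner >= 0) // 2)

    def validate(self, config: SimulationConfig) -> None:
        """Assert the structural invariants (valence, confinement, chain)."""
        p = self.partner
        bonded = np.nonzero(p >= 0)[0]
        if not np.all(p[p[bonded]] == bonded):
            raise ValueError("dynamic-bond registry is not symmetric")
        if len(np.unique(p[bonded])) != len(bonded):
            raise ValueError("valence-1 violation: bead in two bonds")
        r = np.linalg.norm(self.positions, axis=1)
        if np.any(r >= config.R_c):
            raise ValueError("bead outside the confinement sphere")
        if self.n_chain != config.n_chromatin:
            raise ValueError("chain length does not match config")

    def copy(self) -> "SystemState":
        new_rng = np.random.default_rng()
        new_rng.bit_generator.state = self.rng.bit_generator.state
        return SystemState(
            positions=self.positions.copy(),
            velocities=self.velocities.copy(),
            types=self.types.copy(),
            n_chain=self.n_chain,
            partner=self.partner.copy(),
            step=self.step,
            rng=new_rng,
            n_capped=self.n_capped,
        )


@dataclass
class TrajectoryFrame:
    """One dumped configuration."""

    step: int
    positions: np.ndarray
    types: np.ndarray
    partner: np.ndarray


@dataclass
class Trajectory:
    """A sequence of dumped frames plus the per-frame bead types."""

    steps: np.ndarray
    positions: np.ndarray  # (n_frames, N, 3)
    types: np.ndarray  # (N,)
    partners: np.ndarray  # (n_frames, N)
    n_chain: int

    def __len__(self) -> int:
        return len(self.steps)

    def __getitem__(self, i: int) -> TrajectoryFrame:
        return TrajectoryFrame(
            step=int(self.steps[i]),
            positions=self.positions[i],
            types=self.types,
            partner=self.partners[i],
        )

    def __iter__(self):
        for i in range(len(self)):
            yield self[i]
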