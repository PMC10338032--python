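"""Reference (vectorized numpy) potential-energy evaluation.

These functions define the model's energies independently of the neighbor
-list kernels: truncated (not shifted) Lennard-Jones pair potentials with
type-dependent strength and cutoff, harmonic chain springs, a repulsive
LJ wall at the confinement sphere, and harmonic dynamic bonds.  The cell
-list kernels are contractually identical to this path.

Exclusion convention: a pair joined by a chain bond or an *active*
dynamic bond (separation below the rupture radius) does not interact
through the pair potential.  A dynamic bond stretched beyond the rupture
radius contributes no bond energy and its pair interaction resumes; the
next bond sweep removes it.
"""

from __future__ import annotations

import numpy as np

from .config import SimulationConfig, TYPE_NAMES
from .state import EnergyReport, SystemState

_R2_CAP = 0.25  # singularity guard: separations below 0.5 a are clamped


def _lj(r2: np.ndarray, eps4: np.ndarray) -> np.ndarray:
    r2 = np.maximum(r2, _R2_CAP)
    ir6 = 1.0 / r2**3
    return eps4 * (ir6 * ir6 - ir6)


def pair_energy(r: float, type_i, type_j, config: SimulationConfig) -> float:
    """Truncated LJ energy of one pair at separation r (types "A"/"B"/"P"
    or the numeric codes)."""
    if r <= 0:
        raise ValueError("r must be positive")
    ti = TYPE_NAMES.get(type_i, type_i)
    tj = TYPE_NAMES.get(type_j, type_j)
    eps, cut = config.pair_tables()
    if r >= cut[ti, tj]:
        return 0.0
    return float(_lj(np.array(r * r), 4.0 * eps[ti, tj]))


def chain_stretch_energy(state: SystemState, config: SimulationConfig) -> float:
    """U = k_spring * sum (|r_i - r_{i+1}| - a)^2 over the chain bonds."""
    pos = state.positions[: state.n_chain]
    d = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    return float(config.k_spring * np.sum((d - 1.0) ** 2))


def confinement_energy(state: SystemState, config: SimulationConfig) -> float:
    """Repulsive LJ wall acting on the gap R_c - |r_i|."""
    r = np.linalg.norm(state.positions, axis=1)
    gap = config.R_c - r
    if np.any(gap <= 0.0):
        raise ValueError("bead outside the confinement sphere")
    act = gap < 2.0 ** (1.0 / 6.0)
    ig6 = 1.0 / gap[act] ** 6
    return float(np.sum(4.0 * config.eps_confine * (ig6 * ig6 - ig6)))


def dynamic_bond_energy(state: SystemState, config: SimulationConfig) -> float:
    """U = K * sum (|r_a - r_p| - r0)^2 over active dynamic bonds."""
    bonds = state.dynamic_bonds
    if len(bonds) == 0:
        return 0.0
    d = np.linalg.norm(
        state.positions[bonds[:, 0]] - state.positions[bonds[:, 1]], axis=1
    )
    active = d < config.r_break
    return float(config.K * np.sum((d[active] - config.r0) ** 2))


def total_energy(state: SystemState, config: SimulationConfig) -> EnergyReport:
    """All potential-energy components, evaluated over every pair
    (no neighbor list).  Quadratic in bead count; intended for states up
    to a few thousand beads and as the reference the kernels must match.
    """
    pos = state.positions
    n = len(pos)
    eps, cut = config.pair_tables()
    iu, ju = np.triu_indices(n, k=1)
    d2 = np.sum((pos[iu] - pos[ju]) ** 2, axis=1)
    ti, tj = state.types[iu], state.types[ju]
    within = d2 < cut[ti, tj] ** 2
    # exclusions: chain bonds and active dynamic bonds
    chain = (ju - iu == 1) & (ju < state.n_chain)
    bonded = state.partner[iu] == ju
    active_bond = bonded & (d2 < config.r_break**2)
    keep = within & ~chain & ~active_bond
    u_lj = float(np.sum(_lj(d2[keep], 4.0 * eps[ti[keep], tj[keep]])))
    return EnergyReport(
        U_stretch=chain_stretch_energy(state, config),
        U_LJ=u_lj,
        U_confine=confinement_energy(state, config),
        U_bond=dynamic_bond_energy(state, config),
    )
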