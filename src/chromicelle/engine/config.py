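"""Simulation configuration and confinement geometry."""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

TYPE_A, TYPE_B, TYPE_P = 0, 1, 2
TYPE_NAMES = {"A": TYPE_A, "B": TYPE_B, "P": TYPE_P}
TYPE_LABELS = {v: k for k, v in TYPE_NAMES.items()}

#: Default Lennard-Jones strengths (k_B T).  A-A, A-B, B-B and A-P are
#: attractive (cutoff 2.5 a); P-P and B-P are purely repulsive (WCA-style
#: truncation at 2^(1/6) a) — protein beads neither self-associate nor
#: penetrate the inactive cores.
DEFAULT_EPS = {"AA": 0.3, "AB": 0.3, "BB": 0.5, "AP": 0.4, "BP": 1.0, "PP": 1.0}
DEFAULT_REPULSIVE_ONLY = ("BP", "PP")

_CLOSE_PACK = math.pi * math.sqrt(2.0) / 6.0


def confinement_radius(N_chromatin: int, phi: float) -> float:
    """Confinement radius from the chromatin volume fraction.

    phi = N (4/3) pi (a/2)^3 / ((4/3) pi R_c^3), i.e.
    R_c = (N / (8 phi))^(1/3) in units of the bead diameter a.
    """
    if N_chromatin < 1:
        raise ValueError("N_chromatin must be >= 1")
    if not 0.0 < phi <= 1.0:
        raise ValueError(f"phi must be in (0, 1]; got {phi}")
    if phi > _CLOSE_PACK:
        import warnings

        warnings.warn(
            f"phi={phi} exceeds the sphere close-packing bound "
            f"{_CLOSE_PACK:.4f}; the radius is a formal value only",
            stacklevel=2,
        )
    return (N_chromatin / (8.0 * phi)) ** (1.0 / 3.0)


def _pair_key(a: str, b: str) -> str:
    return "".join(sorted((a, b), key="ABP".index))


@dataclass
class SimulationConfig:
    """Full parameterization of a Brownian dynamics run.

    Lengths in bead diameters a, energies in k_B T, times in the reduced
    unit tau.  ``R_c`` is derived from the chromatin volume fraction
    ``phi`` unless given explicitly.  ``K`` is the stiffness of the
    dynamic active-protein bonds; ``K = 0`` means binding is disabled.
    """

    n_blocks: int = 20
    N_A: int = 20
    N_B: int = 20
    N_p: int = 400
    phi: float = 0.01
    R_c: float | None = None
    eps_matrix: dict = field(default_factory=lambda: dict(DEFAULT_EPS))
    repulsive_only: tuple = DEFAULT_REPULSIVE_ONLY
    r_cut_attr: float = 2.5
    r_cut_rep: float = 2.0 ** (1.0 / 6.0)
    k_spring: float = 100.0
    K: float = 5.0
    r0: float = 1.0
    r_bond: float = 1.5
    r_break: float = 2.5
    eps_confine: float = 1.0
    dt: float = 0.01
    damping: float = 10.0
    temperature: float = 1.0
    n_steps: int = 500_000
    bond_update_interval: int = 10
    dump_interval: int = 5000
    log_interval: int = 1000
    skin: float = 0.8
    seed: int = 0
    name: str = "custom"

    def __post_init__(self) -> None:
        if self.n_blocks < 1 or self.N_A < 1 or self.N_B < 1:
            raise ValueError("block pattern fields must be >= 1")
        if self.N_p < 0:
            raise ValueError("N_p must be >= 0")
        if not self.r_bond < self.r_break:
            raise ValueError("r_bond must be smaller than r_break")
        if not self.r0 <= self.r_bond:
            raise ValueError("r0 must not exceed r_bond")
        for name in ("k_spring", "K"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.dt <= 0 or self.damping <= 0 or self.temperature < 0:
            raise ValueError("dt, damping must be positive; temperature >= 0")
        if self.R_c is None:
            self.R_c = confinement_radius(self.n_chromatin, self.phi)
        eps = dict(DEFAULT_EPS)
        eps.update({_pair_key(k[0], k[1]): v for k, v in self.eps_matrix.items()})
        unknown = set(eps) - set(DEFAULT_EPS)
        if unknown:
            raise ValueError(f"unknown eps_matrix keys: {sorted(unknown)}")
        self.eps_matrix = eps

    @property
    def n_chromatin(self) -> int:
        return self.n_blocks * (self.N_A + self.N_B)

    @property
    def n_total(self) -> int:
        return self.n_chromatin + self.N_p

    @property
    def n_active(self) -> int:
        return self.n_blocks * self.N_A

    def pair_tables(self) -> tuple[np.ndarray, np.ndarray]:
        """(eps, cutoff) 3x3 tables indexed by the numeric type codes."""
        eps = np.zeros((3, 3))
        cut = np.zeros((3, 3))
        for key, value in self.eps_matrix.items():
            i, j = TYPE_NAMES[key[0]], TYPE_NAMES[key[1]]
            eps[i, j] = eps[j, i] = value
            rc = self.r_cut_rep if key in self.repulsive_only else self.r_cut_attr
            cut[i, j] = cut[j, i] = rc
        return eps, cut

    def bead_types(self) -> np.ndarray:
        """Per-bead type codes: (A x N_A, B x N_B) repeated, then proteins."""
        block = np.concatenate(
            [np.full(self.N_A, TYPE_A, np.int8), np.full(self.N_B, TYPE_B, np.int8)]
        )
        return np.concatenate(
            [np.tile(block, self.n_blocks), np.full(self.N_p, TYPE_P, np.int8)]
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data = dict(data)
        if "repulsive_only" in data:
            data["repulsive_only"] = tuple(data["repulsive_only"])
        return cls(**data)
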