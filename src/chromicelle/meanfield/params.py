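"""Parameter and result containers for the core-shell mean-field theory."""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np

#: Prefactor convention tag: every scaling ("~") relation is evaluated with
#: numerical prefactor exactly 1, and the osmotic-pressure balance is read as
#: -3/(2 sigma^2 phi_A) + (v_eta/2) phi_A^2 + (w_eta/3) phi_A^3 = 0.
PREFACTOR_CONVENTION = "prefactor-1; pressure-balance v_eta/2, w_eta/3"


class DiluteLimitWarning(UserWarning):
    """Raised when inputs leave the dilute regime the theory assumes."""


class ValidityWarning(UserWarning):
    """Raised when an output falls outside the theory's validity range."""


class NoFiniteThetaPoint(Exception):
    """Binding can never raise v_eta to zero (v <= -4: sup of the
    binding contribution to the second virial coefficient is 4)."""


class RegimeAmbiguityError(Exception):
    """A poor/good-solvent solution was requested inside the theta band."""


class Regime(enum.Enum):
    POOR = "poor"
    THETA = "theta"
    GOOD = "good"


@dataclass(frozen=True)
class SolventRegime:
    """Solvent quality of the active-chromatin shell.

    POOR iff v_eta < -theta_tolerance, GOOD iff v_eta > +theta_tolerance,
    THETA otherwise.
    """

    label: Regime
    theta_tolerance: float = 0.05


@dataclass(frozen=True)
class MeanFieldParams:
    """Dimensionless parameters of the core-shell theory.

    Parameters
    ----------
    N_A, N_B : int
        Monomers per active / inactive block.
    n : int
        Number of blocks of each type.
    v : float
        Bare second virial coefficient of the active monomers, in units of
        a^3.  Must be negative: chromatin is self-attractive in the absence
        of bound protein complexes.
    eps : float
        Binding energy of a protein complex to an active monomer (k_B T).
    phi_bulk : float
        Bulk (reservoir) protein volume fraction.
    phi_B : float
        Monomer volume fraction inside the inactive core (treated as fixed).
    alpha : float
        Dimensionless interfacial tension, alpha = gamma a^2 / k_B T.
    theta_tolerance : float
        Half-width of the band |v_eta| <= theta_tolerance classified as
        theta solvent.
    """

    N_A: int
    N_B: int
    v: float
    eps: float
    phi_bulk: float
    n: int = 1
    phi_B: float = 1.0
    alpha: float = 1.0
    theta_tolerance: float = 0.05

    def __post_init__(self) -> None:
        if self.N_A < 1 or self.N_B < 1 or self.n < 1:
            raise ValueError("block sizes and counts must be >= 1")
        if not self.v < 0:
            raise ValueError(
                "v must be negative (self-attractive chromatin); "
                f"got v={self.v}"
            )
        if not 0.0 < self.phi_bulk < 1.0:
            raise ValueError(f"phi_bulk must be in (0, 1); got {self.phi_bulk}")
        if not 0.0 < self.phi_B <= 1.0:
            raise ValueError(f"phi_B must be in (0, 1]; got {self.phi_B}")
        if not self.alpha > 0:
            raise ValueError(f"alpha must be positive; got {self.alpha}")
        if not self.theta_tolerance > 0:
            raise ValueError("theta_tolerance must be positive")
        if self.phi_bulk > 0.1:
            warnings.warn(
                f"phi_bulk={self.phi_bulk} is outside the dilute-reservoir "
                "limit (<= 0.1) assumed by the theory",
                DiluteLimitWarning,
                stacklevel=2,
            )


@dataclass(frozen=True)
class BindingState:
    """Binding parameter eta and bound fraction Omega = eta/(1+eta)."""

    eta: float
    Omega: float


@dataclass(frozen=True)
class EffectiveVirials:
    """Binding-renormalised virial coefficients of the shell monomers."""

    v_eta: float
    w_eta: float


@dataclass(frozen=True)
class LayerSolution:
    """Scaling solution of the core-shell structure in layer geometry.

    sigma is the interfacial area per block (units a^2), phi_A the shell
    monomer volume fraction, lambda_A = L_A/a the brush extension and
    lambda_B = L_B/a the core half-thickness.  Monomer conservation
    N_A = 2 phi_A lambda_A sigma and N_B = 2 phi_B lambda_B sigma holds
    exactly by construction.
    """

    sigma: float
    phi_A: float
    lambda_A: float
    lambda_B: float
    regime: SolventRegime
    convention: str = PREFACTOR_CONVENTION
    outside_validity: bool = False


@dataclass(frozen=True)
class MicelleSolution:
    """Spherical core-shell domain: m blocks per core, core radius r.

    (4 pi / 3) r^3 phi_B = N_B m holds exactly.
    """

    m: float
    r: float
    regime: SolventRegime


@dataclass(frozen=True)
class ShellThermo:
    """Exchange chemical potentials and osmotic pressures (k_B T units)."""

    mu_fc: float
    mu_bc: float
    mu_bulk: float
    Pi_shell: float
    Pi_bulk: float


@dataclass(frozen=True)
class FullEquilibrium:
    """Converged solution of the four coupled equilibrium conditions.

    The conditions are mu_fc = mu_bc, mu_fc = mu_bulk,
    Pi_shell = Pi_bulk and the interfacial-area condition
    dF/dS + 2 Pi_shell L_A = 0.
    """

    phi_A: float
    lambda_A: float
    lambda_B: float
    sigma: float
    Omega: float
    phi_fc: float
    free_energy_per_block: float
    thermo: ShellThermo
    converged: bool
    residuals: np.ndarray = field(repr=False)

    @property
    def occupancy(self) -> float:
        """Lattice occupancy phi_fc + phi_A (1 + Omega) of the shell."""
        return self.phi_fc + self.phi_A * (1.0 + self.Omega)
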