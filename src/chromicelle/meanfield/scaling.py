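"""Scaling solutions of the core-shell structure.

Layer geometry: the interfacial area per block sigma is set by balancing
the interfacial tension against the osmotic pressure of the brush-like
shell; the shell volume fraction phi_A follows from the dominant balance in
each solvent regime, and the brush extension lambda_A and core
half-thickness lambda_B follow exactly from monomer conservation,

    N_A = 2 phi_A lambda_A sigma,      N_B = 2 phi_B lambda_B sigma.

Spherical micelles: identifying the core radius r with the layer core
thickness gives the number of blocks per core m in each regime, with
(4 pi/3) r^3 phi_B = N_B m.

All "~" relations are evaluated with numerical prefactor exactly 1
(recorded in ``LayerSolution.convention``); scaling exponents do not
depend on this choice.
"""

from __future__ import annotations

import math
import warnings

from scipy.optimize import brentq

from .binding import binding_parameter, classify_regime, effective_virials
from .params import (
    LayerSolution,
    MeanFieldParams,
    MicelleSolution,
    Regime,
    RegimeAmbiguityError,
    SolventRegime,
    ValidityWarning,
)


def shell_volume_fraction(sigma: float, v_eta: float, w_eta: float) -> float:
    """Shell monomer volume fraction from the osmotic-pressure balance.

    Solves the unique positive root of

        -3/(2 sigma^2 phi_A) + (v_eta/2) phi_A^2 + (w_eta/3) phi_A^3 = 0,

    i.e. of g(phi) = (w_eta/3) phi^4 + (v_eta/2) phi^3 - 3/(2 sigma^2).
    The first term is the entropic stretching pressure of the brush; the
    others the two- and three-body monomer interactions.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be positive; got {sigma}")
    if w_eta <= 0:
        raise ValueError(f"w_eta must be positive; got {w_eta}")

    c = 1.5 / sigma**2

    def g(phi: float) -> float:
        return (w_eta / 3.0) * phi**4 + (v_eta / 2.0) * phi**3 - c

    # g(0) = -c < 0 and g is eventually increasing: bracket by doubling.
    hi = 1.0
    while g(hi) <= 0.0:
        hi *= 2.0
        if hi > 1e9:  # pragma: no cover - unreachable for valid inputs
            raise RuntimeError("failed to bracket the positive root")
    phi = brentq(g, 0.0, hi, xtol=1e-300, rtol=8.9e-16, maxiter=200)
    if phi >= 1.0:
        warnings.warn(
            f"phi_A={phi:.4g} >= 1: outside the dilute-shell validity of "
            "the virial expansion",
            ValidityWarning,
            stacklevel=2,
        )
    return phi


def brush_extension(phi_A: float, sigma: float, N_A: float) -> float:
    """Brush extension lambda_A = N_A / (2 phi_A sigma) from conservation
    of active monomers in the shell."""
    if phi_A <= 0 or sigma <= 0 or N_A <= 0:
        raise ValueError("phi_A, sigma and N_A must be positive")
    if phi_A >= 1.0:
        warnings.warn(
            f"phi_A={phi_A} >= 1 is unphysical", ValidityWarning, stacklevel=2
        )
    return N_A / (2.0 * phi_A * sigma)


def core_thickness(sigma: float, N_B: float, phi_B: float) -> float:
    """Core half-thickness lambda_B = N_B / (2 phi_B sigma) from
    conservation of inactive monomers in the core."""
    if sigma <= 0 or N_B <= 0 or phi_B <= 0:
        raise ValueError("sigma, N_B and phi_B must be positive")
    return N_B / (2.0 * phi_B * sigma)


def _regime_sigma_phi(
    regime: Regime, N_A: float, alpha: float, v_eta: float, w_eta: float
) -> tuple[float, float]:
    """(sigma, phi_A) from the regime-specific scaling formulas."""
    if regime is Regime.POOR:
        av = abs(v_eta)
        sigma = w_eta ** (2 / 3) * N_A ** (1 / 3) / (av ** (2 / 3) * alpha ** (1 / 3))
        phi_A = av / w_eta
    elif regime is Regime.GOOD:
        sigma = v_eta ** (2 / 5) * N_A ** (3 / 5) / alpha ** (3 / 5)
        phi_A = 1.0 / (v_eta ** (1 / 3) * sigma ** (2 / 3))
    else:  # THETA
        sigma = w_eta ** (1 / 4) * N_A ** (1 / 2) / alpha ** (1 / 2)
        phi_A = 1.0 / (w_eta ** (1 / 4) * sigma ** (1 / 2))
    return sigma, phi_A


def layer_equilibrium_scaling(
    params: MeanFieldParams, regime: Regime | None = None
) -> LayerSolution:
    """Scaling solution (sigma, phi_A, lambda_A, lambda_B) in layer geometry.

    The solvent regime is classified from the sign of v_eta unless forced
    via ``regime``; forcing a poor- or good-solvent branch inside the theta
    band raises :class:`RegimeAmbiguityError` because the dominant-balance
    assumption behind those branches fails when v_eta ~ 0.
    """
    eta = binding_parameter(params.eps, params.phi_bulk)
    ev = effective_virials(params.v, eta)
    classified = classify_regime(params.v, eta, params.theta_tolerance)
    if regime is None:
        sr = classified
    else:
        if regime is not Regime.THETA and abs(ev.v_eta) <= params.theta_tolerance:
            raise RegimeAmbiguityError(
                f"|v_eta|={abs(ev.v_eta):.3g} <= theta_tolerance="
                f"{params.theta_tolerance}: the {regime.value}-solvent "
                "branch is ill-defined in the theta band"
            )
        sr = SolventRegime(label=regime, theta_tolerance=params.theta_tolerance)

    sigma, phi_A = _regime_sigma_phi(
        sr.label, params.N_A, params.alpha, ev.v_eta, ev.w_eta
    )
    outside = phi_A >= 1.0
    if outside:
        warnings.warn(
            f"phi_A={phi_A:.4g} >= 1: scaling solution outside its "
            "dilute-shell validity range",
            ValidityWarning,
            stacklevel=2,
        )
    lambda_A = params.N_A / (2.0 * phi_A * sigma)
    lambda_B = core_thickness(sigma, params.N_B, params.phi_B)
    return LayerSolution(
        sigma=sigma,
        phi_A=phi_A,
        lambda_A=lambda_A,
        lambda_B=lambda_B,
        regime=sr,
        outside_validity=outside,
    )


def micelle_solution(
    params: MeanFieldParams, regime: Regime | None = None
) -> MicelleSolution:
    """Blocks per spherical core m and core radius r.

    m follows the regime-specific scaling estimate; r is then fixed exactly
    by conservation of inactive monomers, (4 pi/3) r^3 phi_B = N_B m.
    """
    eta = binding_parameter(params.eps, params.phi_bulk)
    ev = effective_virials(params.v, eta)
    if regime is None:
        sr = classify_regime(params.v, eta, params.theta_tolerance)
    else:
        sr = SolventRegime(label=regime, theta_tolerance=params.theta_tolerance)

    N_A, N_B, alpha, phi_B = params.N_A, params.N_B, params.alpha, params.phi_B
    if sr.label is Regime.POOR:
        m = N_B**2 * alpha * ev.v_eta**2 / (N_A * ev.w_eta**2 * phi_B**2)
    elif sr.label is Regime.GOOD:
        m = N_B**2 * alpha ** (9 / 5) / (
            N_A ** (9 / 5) * ev.v_eta ** (6 / 5) * phi_B**2
        )
    else:
        m = N_B**2 * alpha ** (3 / 2) / (
            N_A ** (3 / 2) * ev.w_eta ** (3 / 4) * phi_B**2
        )
    r = (3.0 * N_B * m / (4.0 * math.pi * phi_B)) ** (1 / 3)
    return MicelleSolution(m=m, r=r, regime=sr)
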