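"""Protein-binding equilibrium and the effective virial coefficients.

The binding parameter eta = e**(1+eps) * phi_bulk lumps the binding energy
and reservoir concentration; in the dilute limit the probability that an
active monomer carries a bound complex is Omega = eta/(1+eta).  A bound
complex adds excluded volume to its monomer, renormalising the second and
third virial coefficients of the shell.
"""

from __future__ import annotations

import math

from .params import (
    BindingState,
    EffectiveVirials,
    NoFiniteThetaPoint,
    Regime,
    SolventRegime,
)


def binding_parameter(eps: float, phi_bulk: float) -> float:
    """Binding parameter eta = e**(1 + eps) * phi_bulk.

    ``eps`` is the binding energy gain (k_B T) of a complex on an active
    monomer; ``phi_bulk`` the reservoir protein volume fraction.
    """
    if phi_bulk < 0:
        raise ValueError(f"phi_bulk must be non-negative; got {phi_bulk}")
    return math.exp(1.0 + eps) * phi_bulk


def bound_fraction(eta: float) -> float:
    """Fraction of active monomers bound to a complex, Omega = eta/(1+eta)."""
    if eta < 0:
        raise ValueError(f"eta must be non-negative; got {eta}")
    return eta / (1.0 + eta)


def binding_state(eps: float, phi_bulk: float) -> BindingState:
    eta = binding_parameter(eps, phi_bulk)
    return BindingState(eta=eta, Omega=bound_fraction(eta))


def effective_virials(v: float, eta: float) -> EffectiveVirials:
    """Binding-renormalised virial coefficients.

    v_eta = v + (1+2 eta)^2/(1+eta)^2 and w_eta = (1+2 eta)^3/(1+eta)^3.
    Since (1+2 eta)/(1+eta) = 1 + Omega, these are the bare coefficients
    augmented by the excluded volume of monomer-plus-bound-complex units:
    v_eta runs from v+1 (no binding) to v+4 (saturation) and w_eta from
    1 to 8, both nondecreasing in eta.
    """
    if eta < 0:
        raise ValueError(f"eta must be non-negative; got {eta}")
    ratio = (1.0 + 2.0 * eta) / (1.0 + eta)
    return EffectiveVirials(v_eta=v + ratio**2, w_eta=ratio**3)


def theta_point(v: float) -> float:
    """Binding parameter eta* at which the effective second virial
    coefficient vanishes (theta-solvent condition v_eta(eta*) = 0).

    Solving v + ((1+2 eta)/(1+eta))^2 = 0 gives the closed form
    eta* = (sqrt(-v) - 1) / (2 - sqrt(-v)).

    Returns 0.0 when v > -1 (the shell is already in good solvent at zero
    binding) and raises :class:`NoFiniteThetaPoint` when v <= -4, where the
    binding contribution (bounded above by 4) can never cancel v.
    """
    if v >= 0:
        raise ValueError(f"v must be negative; got {v}")
    if v > -1.0:
        return 0.0
    if v <= -4.0:
        raise NoFiniteThetaPoint(
            f"v={v} <= -4: v_eta < 0 for all finite eta (no theta point)"
        )
    s = math.sqrt(-v)
    return (s - 1.0) / (2.0 - s)


def classify_regime(
    v: float, eta: float, theta_tolerance: float = 0.05
) -> SolventRegime:
    """Classify the shell solvent quality by the sign of v_eta.

    A band |v_eta| <= theta_tolerance is labelled THETA; outside it the
    sign of v_eta selects POOR (collapsed) or GOOD (swollen).
    """
    if theta_tolerance <= 0:
        raise ValueError("theta_tolerance must be positive")
    v_eta = effective_virials(v, eta).v_eta
    if v_eta < -theta_tolerance:
        label = Regime.POOR
    elif v_eta > theta_tolerance:
        label = Regime.GOOD
    else:
        label = Regime.THETA
    return SolventRegime(label=label, theta_tolerance=theta_tolerance)
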