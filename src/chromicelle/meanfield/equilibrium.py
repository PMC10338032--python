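"""Full numerical solution of the core-shell equilibrium conditions.

The free energy per block (a = 1, k_B T = 1), with per-block interfacial
area sigma, brush extension lambda_A, bound fraction Omega, free-complex
volume fraction phi_fc in the shell solvent and shell monomer volume
fraction phi_A = N_A/(2 lambda_A sigma), is

    f = 2 alpha sigma                                     (core interface)
      + 2 lambda_A sigma [phi_fc ln phi_fc + psi ln psi]  (mixing entropy)
      + N_A [Omega ln Omega + (1-Omega) ln(1-Omega) - eps Omega]  (binding)
      + 3 lambda_A^2 / N_A + v N_A phi_A (1-Omega)^2 / 2  (brush)

with psi = 1 - phi_fc - phi_A (1 + Omega) the solvent fraction (a bound
complex occupies one lattice site next to its monomer).  Equilibrium with
the protein reservoir (mu_bulk = ln phi_bulk, Pi_bulk = phi_bulk) requires

    mu_fc = mu_bc,   mu_fc = mu_bulk,   Pi_shell = Pi_bulk,
    dF/dS + 2 Pi_shell L_A = 0,

all derivatives taken analytically below.  The solver works in transformed
variables (logits of compositions, logs of lengths) so iterates stay
feasible, and never clamps a result: non-convergence is reported as such.
"""

from __future__ import annotations

import math
from dataclasses import replace

import numpy as np
from scipy.optimize import root

from .binding import binding_parameter, bound_fraction
from .params import FullEquilibrium, MeanFieldParams, ShellThermo
from .scaling import core_thickness, layer_equilibrium_scaling

_TINY = 1e-300


def _psi(phi_fc: float, phi_A: float, Omega: float) -> float:
    return 1.0 - phi_fc - phi_A * (1.0 + Omega)


def shell_thermo(
    params: MeanFieldParams,
    phi_fc: float,
    Omega: float,
    lambda_A: float,
    sigma: float,
) -> ShellThermo:
    """Chemical potentials and osmotic pressures of a candidate shell state.

    phi_A is eliminated through conservation of active monomers,
    phi_A = N_A/(2 lambda_A sigma).  Raises on lattice-occupancy violation
    (the mixing entropy would take the log of a non-positive argument).
    """
    N_A, v = params.N_A, params.v
    phi_A = N_A / (2.0 * lambda_A * sigma)
    psi = _psi(phi_fc, phi_A, Omega)
    if psi <= 0.0 or phi_fc <= 0.0:
        raise ValueError(
            f"occupancy violation: phi_fc={phi_fc:.4g}, "
            f"phi_A(1+Omega)={phi_A * (1 + Omega):.4g} leave no solvent"
        )
    x = phi_fc + phi_A * (1.0 + Omega)
    log_psi = math.log(psi)

    mu_fc = math.log(phi_fc) - log_psi
    if 0.0 < Omega < 1.0:
        mu_bc = (
            -(log_psi + 1.0)
            + math.log(Omega / (1.0 - Omega))
            - params.eps
            - v * phi_A * (1.0 - Omega)
        )
    else:
        mu_bc = math.nan  # ideal-binding entropy diverges at Omega in {0, 1}
    Pi_shell = (
        phi_fc
        - psi * log_psi
        - (log_psi + 1.0) * x
        - 3.0 * lambda_A / (sigma * N_A)
        + 0.5 * v * phi_A**2 * (1.0 - Omega) ** 2
    )
    return ShellThermo(
        mu_fc=mu_fc,
        mu_bc=mu_bc,
        mu_bulk=math.log(params.phi_bulk),
        Pi_shell=Pi_shell,
        Pi_bulk=params.phi_bulk,
    )


def _area_derivative(
    params: MeanFieldParams,
    phi_fc: float,
    Omega: float,
    lambda_A: float,
    sigma: float,
) -> float:
    """d(f)/d(sigma) at fixed lambda_A and particle numbers (per block)."""
    N_A, v = params.N_A, params.v
    phi_A = N_A / (2.0 * lambda_A * sigma)
    psi = _psi(phi_fc, phi_A, Omega)
    x = phi_fc + phi_A * (1.0 + Omega)
    log_psi = math.log(max(psi, _TINY))
    return (
        2.0 * params.alpha
        - 2.0 * lambda_A * phi_fc
        + 2.0 * lambda_A * (psi * log_psi + (log_psi + 1.0) * x)
        - v * lambda_A * phi_A**2 * (1.0 - Omega) ** 2
    )


def free_energy_per_block(
    params: MeanFieldParams,
    phi_fc: float,
    Omega: float,
    lambda_A: float,
    sigma: float,
) -> float:
    """Free energy per block of the core-shell structure (k_B T)."""
    N_A, v = params.N_A, params.v
    phi_A = N_A / (2.0 * lambda_A * sigma)
    psi = _psi(phi_fc, phi_A, Omega)
    f_core = 2.0 * params.alpha * sigma
    f_mix = 2.0 * lambda_A * sigma * (
        phi_fc * math.log(max(phi_fc, _TINY))
        + psi * math.log(max(psi, _TINY))
    )
    if 0.0 < Omega < 1.0:
        s_bind = Omega * math.log(Omega) + (1.0 - Omega) * math.log(1.0 - Omega)
    else:
        s_bind = 0.0
    f_bind = N_A * (s_bind - params.eps * Omega)
    f_brush = 3.0 * lambda_A**2 / N_A + 0.5 * v * N_A * phi_A * (1.0 - Omega) ** 2
    return f_core + f_mix + f_bind + f_brush


def _residuals(
    params: MeanFieldParams,
    phi_fc: float,
    Omega: float,
    lambda_A: float,
    sigma: float,
    binding: bool,
) -> np.ndarray:
    """Raw residuals of the equilibrium conditions (unscaled)."""
    N_A, v = params.N_A, params.v
    phi_A = N_A / (2.0 * lambda_A * sigma)
    psi = _psi(phi_fc, phi_A, Omega)
    if psi <= 0.0 or phi_fc <= 0.0:
        # infeasible iterate: steer back smoothly with a large penalty
        pen = 1e6 * (1.0 + abs(psi))
        return np.full(4 if binding else 3, pen)
    th = shell_thermo(params, phi_fc, Omega, lambda_A, sigma)
    dfds = _area_derivative(params, phi_fc, Omega, lambda_A, sigma)
    r_area = dfds + 2.0 * th.Pi_shell * lambda_A
    r_pressure = th.Pi_shell - th.Pi_bulk
    r_reservoir = th.mu_fc - th.mu_bulk
    if binding:
        return np.array(
            [th.mu_fc - th.mu_bc, r_reservoir, r_pressure, r_area]
        )
    return np.array([r_reservoir, r_pressure, r_area])


def _residual_scales(
    params: MeanFieldParams,
    phi_fc: float,
    Omega: float,
    lambda_A: float,
    sigma: float,
    binding: bool,
) -> np.ndarray:
    """Magnitude scales used to report residuals relative to their terms."""
    th = shell_thermo(params, phi_fc, Omega, lambda_A, sigma)
    N_A = params.N_A
    phi_A = N_A / (2.0 * lambda_A * sigma)
    s_mu = max(1.0, abs(th.mu_fc), abs(th.mu_bulk))
    s_pi = max(
        abs(th.Pi_bulk),
        3.0 * lambda_A / (sigma * N_A),
        0.5 * abs(params.v) * phi_A**2,
    )
    s_area = max(2.0 * params.alpha, 6.0 * lambda_A**2 / (sigma * N_A))
    if binding:
        s_mu1 = max(1.0, abs(th.mu_fc), abs(th.mu_bc) if math.isfinite(th.mu_bc) else 1.0)
        return np.array([s_mu1, s_mu, s_pi, s_area])
    return np.array([s_mu, s_pi, s_area])


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def _expit(x: float) -> float:
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


def full_equilibrium(
    params: MeanFieldParams,
    binding: bool = True,
    tol: float = 1e-10,
    max_restarts: int = 8,
) -> FullEquilibrium:
    """Solve the four coupled equilibrium conditions.

    The initial guess comes from the scaling solution
    (:func:`layer_equilibrium_scaling`) and the dilute-limit bound fraction
    Omega = eta/(1+eta).  With ``binding=False`` the bound fraction is
    frozen at zero and only reservoir exchange of free complexes, pressure
    balance and the area condition are solved (the bare-brush system).

    Returns a :class:`FullEquilibrium` whose ``converged`` flag certifies
    that the max-norm of the term-scaled residual vector is below ``tol``;
    a failed solve is reported with ``converged=False``, never silently.
    """
    eta = binding_parameter(params.eps, params.phi_bulk)
    Omega0 = bound_fraction(eta) if binding else 0.0
    Omega0 = min(max(Omega0, 1e-12), 1.0 - 1e-12)
    import warnings as _w

    with _w.catch_warnings():
        _w.simplefilter("ignore")
        scal = layer_equilibrium_scaling(params)
    lam0 = scal.lambda_A
    sig0 = scal.sigma
    phi_fc0 = min(params.phi_bulk, 0.5)

    def pack(phi_fc, Omega, lam, sig):
        u = [_logit(phi_fc), math.log(lam), math.log(sig)]
        if binding:
            u.insert(1, _logit(Omega))
        return np.array(u)

    def unpack(u):
        # clip the log-variables so stray solver excursions cannot
        # overflow; the solution is always far inside these bounds
        if binding:
            return (
                _expit(u[0]),
                _expit(u[1]),
                math.exp(min(max(u[2], -40.0), 40.0)),
                math.exp(min(max(u[3], -40.0), 40.0)),
            )
        return (
            _expit(u[0]),
            0.0,
            math.exp(min(max(u[1], -40.0), 40.0)),
            math.exp(min(max(u[2], -40.0), 40.0)),
        )

    def fun(u):
        phi_fc, Omega, lam, sig = unpack(u)
        return _residuals(params, phi_fc, Omega, lam, sig, binding)

    rng = np.random.default_rng(0)  # deterministic restart jitter
    best = None
    for attempt in range(max_restarts):
        if attempt == 0:
            u0 = pack(phi_fc0, Omega0, lam0, sig0)
        else:
            jit = rng.normal(scale=0.3 * attempt, size=4 if binding else 3)
            u0 = pack(phi_fc0, Omega0, lam0, sig0) + jit
        sol = root(fun, u0, method="hybr", options={"xtol": 1e-15, "maxfev": 4000})
        phi_fc, Omega, lam, sig = unpack(sol.x)
        try:
            raw = _residuals(params, phi_fc, Omega, lam, sig, binding)
            scales = _residual_scales(params, phi_fc, Omega, lam, sig, binding)
        except ValueError:
            continue
        scaled = np.abs(raw) / scales
        if best is None or scaled.max() < best[0]:
            best = (scaled.max(), phi_fc, Omega, lam, sig, scaled)
        if scaled.max() < tol:
            break

    assert best is not None
    worst, phi_fc, Omega, lam, sig = best[0], best[1], best[2], best[3], best[4]
    scaled = best[5]
    converged = bool(worst < tol)
    th = shell_thermo(params, phi_fc, Omega, lam, sig)
    phi_A = params.N_A / (2.0 * lam * sig)
    return FullEquilibrium(
        phi_A=phi_A,
        lambda_A=lam,
        lambda_B=core_thickness(sig, params.N_B, params.phi_B),
        sigma=sig,
        Omega=Omega,
        phi_fc=phi_fc,
        free_energy_per_block=free_energy_per_block(
            params, phi_fc, Omega, lam, sig
        ),
        thermo=th,
        converged=converged,
        residuals=scaled,
    )


def sweep(
    params: MeanFieldParams,
    param: str,
    values,
    full: bool = False,
):
    """Sweep one parameter, returning a tidy DataFrame of observables.

    ``param`` may be any :class:`MeanFieldParams` field or ``"eta"`` (swept
    directly through the binding parameter at fixed phi_bulk, adjusting
    eps).  Columns: eta, Omega, v_eta, w_eta, regime, sigma, phi_A,
    lambda_A, lambda_B, m, r, plus full-equilibrium columns when
    ``full=True``.
    """
    import pandas as pd

    from .binding import effective_virials
    from .scaling import micelle_solution

    rows = []
    for val in values:
        if param == "eta":
            if val < 0:
                raise ValueError("eta must be non-negative")
            if val == 0:
                eps = -745.0  # exp(1+eps)*phi_bulk underflows to eta = 0
            else:
                eps = math.log(val / params.phi_bulk) - 1.0
            p = replace(params, eps=eps)
        else:
            p = replace(params, **{param: val})
        eta = binding_parameter(p.eps, p.phi_bulk)
        ev = effective_virials(p.v, eta)
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore")
            lay = layer_equilibrium_scaling(p)
            mic = micelle_solution(p)
        row = {
            param: val,
            "eta": eta,
            "Omega": bound_fraction(eta),
            "v_eta": ev.v_eta,
            "w_eta": ev.w_eta,
            "regime": lay.regime.label.value,
            "sigma": lay.sigma,
            "phi_A": lay.phi_A,
            "lambda_A": lay.lambda_A,
            "lambda_B": lay.lambda_B,
            "m": mic.m,
            "r": mic.r,
        }
        if full:
            eq = full_equilibrium(p)
            row.update(
                eq_sigma=eq.sigma,
                eq_phi_A=eq.phi_A,
                eq_lambda_A=eq.lambda_A,
                eq_lambda_B=eq.lambda_B,
                eq_Omega=eq.Omega,
                eq_phi_fc=eq.phi_fc,
                eq_converged=eq.converged,
            )
        rows.append(row)
    return pd.DataFrame(rows)
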