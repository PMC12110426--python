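"""Freidlin-Wentzell weak-noise machinery.

For D -> 0 the stationary measure takes the WKB form
P ~ exp(-(H0 + D H1 + ...)/D) with the quasipotential H0 solving a
stationary Hamilton-Jacobi equation for the Freidlin-Wentzell Hamiltonian
H_FW(x, p) = |p|^2 + F(x).p (momenta p_i = (xdot_i - F_i)/2), and H1
solving the associated transport equation.  The mixed-Hessian trace of
H_FW on the p = 0 subspace equals div F: the divergence of the
generalized forces is exactly the phase-space compression that modulates
the weak-noise propagator amplitude.

No Hamilton-Jacobi boundary-value solver is included; H0 enters as a
closed form (H0 = V for perpendicular-HHD systems) or as an empirical
D*h surrogate.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .fields import ScalarField, SystemSpec

__all__ = [
    "fw_hamiltonian",
    "compression_trace",
    "hj_residual",
    "transport_residual",
    "solve_H1_characteristics",
    "amplitude_along",
    "first_order_velocity",
]

CRITICAL_SET_TOL = 1e-10  # guard on |grad H0|^2


def fw_hamiltonian(system: SystemSpec, x, p) -> np.ndarray:
    """H_FW(x, p) = |p|^2 + F(x) . p."""
    x = np.asarray(x, dtype=float)
    p = np.asarray(p, dtype=float)
    if x.shape != p.shape:
        raise ValueError("x and p must have matching shapes")
    return np.einsum("...i,...i->...", p, p) + np.einsum(
        "...i,...i->...", system.F(x), p)


def compression_trace(system: SystemSpec, x, fd_step: float = 1e-5):
    """Trace of the mixed Hessian d^2 H_FW / dx dp at p = 0.

    Returns ``(closed, numeric)``: the closed-form route div F(x) and a
    central-finite-difference evaluation of the mixed Hessian trace of
    H_FW itself, exposed separately so the identity can be tested.
    """
    x = np.asarray(x, dtype=float)
    closed = float(system.F.divergence(x))
    n = system.dim
    h = fd_step
    tr = 0.0
    for i in range(n):
        e = np.zeros(n)
        e[i] = h
        # d/dx_i d/dp_i H_FW at p=0 via 4-point stencil
        tr += (
            fw_hamiltonian(system, x + e, e)
            - fw_hamiltonian(system, x + e, -e)
            - fw_hamiltonian(system, x - e, e)
            + fw_hamiltonian(system, x - e, -e)
        ) / (4.0 * h * h)
    return closed, float(tr)


def hj_residual(system: SystemSpec, H0: ScalarField, points) -> np.ndarray:
    """Stationary Hamilton-Jacobi residual F . grad H0 + (grad H0)^2.

    Zero identifies a stationary quasipotential; for a perpendicular-HHD
    system H0 = V gives -(grad V)^2 + u.grad V + (grad V)^2 = 0
    identically.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    g = H0.gradient(pts)
    return (np.einsum("...i,...i->...", system.F(pts), g)
            + np.einsum("...i,...i->...", g, g))


def transport_residual(system: SystemSpec, H0: ScalarField, H1: ScalarField,
                       points) -> np.ndarray:
    """Stationary transport-equation residual

        div F - 2 grad H0 . grad H1 - F . grad H1 + Lap H0

    which is the O(D^0) coefficient of the stationary Fokker-Planck
    operator applied to exp(-(H0/D + H1)); it vanishes iff H1 is a valid
    subleading correction.  With this form a perpendicular-HHD system
    (H0 = V) reduces to -(grad V + u) . grad H1 = 0, i.e. H1 constant,
    consistent with the exact Boltzmann solution; for linear drift F = Ax
    with stationary covariance D*S it reduces to Tr(A) + Tr(S^-1) = 0 at
    H1 = 0, an identity of the Lyapunov equation.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    g0 = H0.gradient(pts)
    g1 = H1.gradient(pts)
    return (system.F.divergence(pts)
            - 2.0 * np.einsum("...i,...i->...", g0, g1)
            - np.einsum("...i,...i->...", system.F(pts), g1)
            + H0.laplacian(pts))


def solve_H1_characteristics(system: SystemSpec, H0: ScalarField,
                             base_point, query_points, **kwargs):
    """Transport correction H1 along characteristics of the auxiliary
    ascent flow.

    The stationary transport equation fixes only the directional
    derivative (2 grad H0 + F) . grad H1 = div F + Lap H0, the same
    structure as the W_r line integral (one integrator, two equations);
    H1 is obtained by descending the attracting flow -(2 grad H0 + F)
    from the query points to the base region, with H1(base) = 0.  For a
    perpendicular-HHD system the ascent flow is grad V + u and the
    source vanishes identically, so H1 is constant.
    """
    from .stationary import descent_line_integral

    def ascent(x):
        return 2.0 * H0.gradient(x) + system.F(x)

    def source(x):
        return float(system.F.divergence(x)) + float(H0.laplacian(x))

    return descent_line_integral(ascent, source, base_point, query_points,
                                 **kwargs)


def amplitude_along(system: SystemSpec, times, path) -> np.ndarray:
    """Weak-noise propagator amplitude factor exp(-int_0^t div F dt')
    accumulated by trapezoidal quadrature along a supplied path."""
    t = np.asarray(times, dtype=float)
    X = np.asarray(path, dtype=float)
    if t.ndim != 1 or X.shape[0] != t.shape[0]:
        raise ValueError("times and path lengths must match")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    divF = system.F.divergence(X)
    integral = np.concatenate(
        [[0.0], np.cumsum(0.5 * (divF[1:] + divF[:-1]) * np.diff(t))])
    return np.exp(-integral)


def first_order_velocity(system: SystemSpec, H0: ScalarField,
                         H1: Optional[ScalarField], x,
                         tol: float = CRITICAL_SET_TOL):
    """Zeroth- and first-order typical velocities of the weak-noise
    expansion X = X0 + D X1 + O(D^2):

        Xdot0 = F + grad H0
        Xdot1 = grad H1 + q grad H0,   q = -(div F + Lap H0) / |grad H0|^2

    The representative returned is the minimal one: any field orthogonal
    to grad H0 may be added to Xdot1 without affecting the transport
    balance.  Raises near the critical set grad H0 = 0.
    """
    x = np.asarray(x, dtype=float)
    g0 = H0.gradient(x)
    g0sq = float(np.einsum("...i,...i->...", g0, g0))
    if g0sq < tol:
        raise ValueError(
            f"|grad H0|^2 = {g0sq:.3g} below tolerance at {x.tolist()}: "
            "first-order correction undefined near the critical set"
        )
    Xdot0 = system.F(x) + g0
    q = -(float(system.F.divergence(x)) + float(H0.laplacian(x))) / g0sq
    g1 = H1.gradient(x) if H1 is not None else np.zeros_like(g0)
    Xdot1 = g1 + q * g0
    return Xdot0, Xdot1
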