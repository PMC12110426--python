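"""Model zoo: the worked planar systems plus general constructions that
carry an orthogonal Helmholtz-Hodge decomposition (perpendicular HHD) by
design.

All built-ins are two-dimensional; the general constructors
(:func:`linear_normal_system`, :func:`from_potential_antisym`) work in any
dimension.  Note the Brusselator's kinetic rate constant -- often printed
as lambda in the chemical-oscillator literature -- is exposed here as
``b`` so it cannot be confused with the perturbation strength ``lam`` of
the near-HHD class.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .fields import (
    Box,
    ConsistencyError,
    ScalarField,
    SystemSpec,
    VectorField,
    assemble_system,
)

__all__ = ["make_model", "linear_normal_system", "from_potential_antisym", "MODEL_NAMES"]

MODEL_NAMES = (
    "gradient_quadratic",
    "hopf",
    "suda_quadratic",
    "brusselator",
    "linear_example",
)


def _rotation_u(omega: float) -> VectorField:
    # u = Omega_matrix @ x with Omega_matrix = [[0, w], [-w, 0]]
    def fn(p):
        p = np.asarray(p, dtype=float)
        return np.stack([omega * p[..., 1], -omega * p[..., 0]], axis=-1)

    def jac(p):
        p = np.asarray(p, dtype=float)
        J = np.zeros(p.shape + (2,))
        J[..., 0, 1] = omega
        J[..., 1, 0] = -omega
        return J

    return VectorField(
        fn=fn, dim=2, jac=jac, div=lambda p: np.zeros(np.asarray(p).shape[:-1]),
        name="rotation",
    )


def _gradient_quadratic(k: float, D: float, **_) -> SystemSpec:
    V = ScalarField(
        fn=lambda p: 0.5 * k * np.sum(np.asarray(p, dtype=float) ** 2, axis=-1),
        dim=2,
        grad=lambda p: k * np.asarray(p, dtype=float),
        lap=lambda p: np.full(np.asarray(p).shape[:-1], 2.0 * k),
        name="V=k|x|^2/2",
    )
    return assemble_system(
        V=V, D=D, name="gradient_quadratic", params={"k": k, "D": D},
        domain=Box((-4.0, -4.0), (4.0, 4.0)),
    )


def _hopf(A: float, B: float, Omega: float, D: float, **_) -> SystemSpec:
    """Noisy Hopf oscillator: radial pitchfork flow plus rigid rotation.

    V = -(A/2)|x|^2 + (B/4)|x|^4, u = [[0, Omega], [-Omega, 0]] x; the
    rotation is tangent to the level sets of V, so the pair is a
    perpendicular HHD for any A, B, Omega.
    """
    def V_fn(p):
        r2 = np.sum(np.asarray(p, dtype=float) ** 2, axis=-1)
        return -0.5 * A * r2 + 0.25 * B * r2**2

    def V_grad(p):
        p = np.asarray(p, dtype=float)
        r2 = np.sum(p**2, axis=-1)
        return (-A + B * r2)[..., None] * p

    def V_lap(p):
        r2 = np.sum(np.asarray(p, dtype=float) ** 2, axis=-1)
        return -2.0 * A + 4.0 * B * r2

    V = ScalarField(fn=V_fn, dim=2, grad=V_grad, lap=V_lap, name="V_hopf")
    return assemble_system(
        V=V, u=_rotation_u(Omega), D=D, name="hopf",
        params={"A": A, "B": B, "Omega": Omega, "D": D},
        domain=Box((-2.0, -2.0), (2.0, 2.0)),
    )


# Quadratic planar flow with an exact perpendicular HHD (Suda's example).
# F = (x^2 - 2xy + 3y^2, 4x^2 - 4xy + 2y^2); the declared parts carry an
# overall polynomial prefactor of 1/26 and V is the cubic whose gradient
# reproduces the declared -gradV.
def _suda_quadratic(D: float, **_) -> SystemSpec:
    c = 1.0 / 26.0

    def V_fn(p):
        p = np.asarray(p, dtype=float)
        x, y = p[..., 0], p[..., 1]
        return c * (19.0 / 3.0 * x**3 - 9.0 * x**2 * y + 7.0 * x * y**2
                    - 17.0 / 3.0 * y**3)

    def V_grad(p):
        p = np.asarray(p, dtype=float)
        x, y = p[..., 0], p[..., 1]
        return c * np.stack(
            [19.0 * x**2 - 18.0 * x * y + 7.0 * y**2,
             -9.0 * x**2 + 14.0 * x * y - 17.0 * y**2], axis=-1)

    def V_lap(p):
        p = np.asarray(p, dtype=float)
        x, y = p[..., 0], p[..., 1]
        return c * (38.0 * x - 18.0 * y + 14.0 * x - 34.0 * y)

    def u_fn(p):
        p = np.asarray(p, dtype=float)
        x, y = p[..., 0], p[..., 1]
        return c * np.stack(
            [45.0 * x**2 - 70.0 * x * y + 85.0 * y**2,
             95.0 * x**2 - 90.0 * x * y + 35.0 * y**2], axis=-1)

    def u_div(p):
        p = np.asarray(p, dtype=float)
        x, y = p[..., 0], p[..., 1]
        return c * ((90.0 * x - 70.0 * y) + (-90.0 * x + 70.0 * y))

    def F_fn(p):
        p = np.asarray(p, dtype=float)
        x, y = p[..., 0], p[..., 1]
        return np.stack(
            [x**2 - 2.0 * x * y + 3.0 * y**2,
             4.0 * x**2 - 4.0 * x * y + 2.0 * y**2], axis=-1)

    V = ScalarField(fn=V_fn, dim=2, grad=V_grad, lap=V_lap, name="V_suda")
    u = VectorField(fn=u_fn, dim=2, div=u_div, name="u_suda")
    def F_div(p):
        p = np.asarray(p, dtype=float)
        return -2.0 * p[..., 0] + 2.0 * p[..., 1]

    F = VectorField(fn=F_fn, dim=2, div=F_div, name="F_suda")
    return assemble_system(
        F=F, V=V, u=u, D=D, name="suda_quadratic", params={"D": D},
        domain=Box((-2.0, -2.0), (2.0, 2.0)),
    )


def _brusselator(mu: float, b: float, D: float, **_) -> SystemSpec:
    """Planar Brusselator, F = (mu + x^2 y - (b+1) x, b x - x^2 y).

    No decomposition parts are declared: this flow admits no perpendicular
    HHD with polynomial fields.  Fixed point at (mu, b/mu).
    """
    if mu <= 0 or b <= 0:
        raise ValueError("brusselator parameters mu, b must be positive")

    def F_fn(p):
        p = np.asarray(p, dtype=float)
        x, y = p[..., 0], p[..., 1]
        return np.stack(
            [mu + x**2 * y - (b + 1.0) * x, b * x - x**2 * y], axis=-1)

    def F_div(p):
        p = np.asarray(p, dtype=float)
        x, y = p[..., 0], p[..., 1]
        return 2.0 * x * y - (b + 1.0) - x**2

    def F_jac(p):
        p = np.asarray(p, dtype=float)
        x, y = p[..., 0], p[..., 1]
        J = np.empty(p.shape + (2,))
        J[..., 0, 0] = 2.0 * x * y - (b + 1.0)
        J[..., 0, 1] = x**2
        J[..., 1, 0] = b - 2.0 * x * y
        J[..., 1, 1] = -(x**2)
        return J

    F = VectorField(fn=F_fn, dim=2, jac=F_jac, div=F_div, name="F_brusselator")
    return assemble_system(
        F=F, D=D, name="brusselator", params={"mu": mu, "b": b, "D": D},
        domain=Box((0.0, 0.0), (5.0, 6.0)),
    )


def _linear_example(Omega: float, lam: float, D: float, **_) -> SystemSpec:
    """Linear near-HHD testbed: V = |x|^2/2, u a rigid rotation, r = (y, 0).

    This is the Hopf oscillator with A = -1, B = 0 plus the 'relevant,
    active' shear perturbation; its exact stationary measure is Gaussian,
    which makes it the workhorse oracle system for the perturbative
    stationary machinery.
    """
    V = ScalarField(
        fn=lambda p: 0.5 * np.sum(np.asarray(p, dtype=float) ** 2, axis=-1),
        dim=2,
        grad=lambda p: np.asarray(p, dtype=float),
        lap=lambda p: np.full(np.asarray(p).shape[:-1], 2.0),
        name="V=|x|^2/2",
    )

    def r_fn(p):
        p = np.asarray(p, dtype=float)
        return np.stack([p[..., 1], np.zeros_like(p[..., 1])], axis=-1)

    r = VectorField(
        fn=r_fn, dim=2, div=lambda p: np.zeros(np.asarray(p).shape[:-1]),
        name="r=(y,0)",
    )
    return assemble_system(
        V=V, u=_rotation_u(Omega), r=r, lam=lam, D=D, name="linear_example",
        params={"Omega": Omega, "lambda": lam, "D": D},
        domain=Box((-4.0, -4.0), (4.0, 4.0)),
    )


_BUILDERS = {
    "gradient_quadratic": _gradient_quadratic,
    "hopf": _hopf,
    "suda_quadratic": _suda_quadratic,
    "brusselator": _brusselator,
    "linear_example": _linear_example,
}

_DEFAULTS = {
    "gradient_quadratic": {"k": 1.0, "D": 0.5},
    "hopf": {"A": 1.0, "B": 1.0, "Omega": 2.0, "D": 0.1},
    "suda_quadratic": {"D": 0.1},
    "brusselator": {"mu": 1.0, "b": 3.0, "D": 0.005},
    "linear_example": {"Omega": 1.0, "lam": 0.0, "D": 0.1},
}


def make_model(name: str, **params) -> SystemSpec:
    """Construct a zoo system by name, with defaults mirroring the worked
    parameter sets (hopf: A=B=1; brusselator: mu=1, b=3, D=0.005; ...)."""
    if name not in _BUILDERS:
        raise ValueError(f"unknown model {name!r}; known: {sorted(_BUILDERS)}")
    kwargs = dict(_DEFAULTS[name])
    # accept the chemists' symbol for the Brusselator rate as an alias
    if name == "brusselator" and "lambda_rate" in params:
        params["b"] = params.pop("lambda_rate")
    if name == "linear_example" and "lambda" in params:
        params["lam"] = params.pop("lambda")
    unknown = set(params) - set(kwargs)
    if unknown:
        raise ValueError(f"unknown parameters for {name!r}: {sorted(unknown)}")
    kwargs.update(params)
    return _BUILDERS[name](**kwargs)


def linear_normal_system(A_matrix, D: float, tol: float = 1e-10) -> SystemSpec:
    """System with linear drift F = A x for a normal matrix A.

    A normal A splits into symmetric and antisymmetric parts that commute,
    giving V = -(1/2) x^T A_sym x and u = A_anti x with u perpendicular to
    grad(V) -- a perpendicular HHD.  Non-normal matrices are rejected with
    the commutator norm.
    """
    A = np.asarray(A_matrix, dtype=float)
    n = A.shape[0]
    if A.shape != (n, n):
        raise ValueError("A_matrix must be square")
    comm = A @ A.T - A.T @ A
    cnorm = float(np.linalg.norm(comm))
    if cnorm > tol * max(1.0, float(np.linalg.norm(A)) ** 2):
        raise ConsistencyError(
            f"matrix is not normal: ||[A, A^T]|| = {cnorm:.6g}"
        )
    S = 0.5 * (A + A.T)
    K = 0.5 * (A - A.T)

    V = ScalarField(
        fn=lambda p: -0.5 * np.einsum("...i,ij,...j->...", np.asarray(p, float), S,
                                      np.asarray(p, float)),
        dim=n,
        grad=lambda p: -np.asarray(p, float) @ S.T,
        lap=lambda p: np.full(np.asarray(p).shape[:-1], -float(np.trace(S))),
        name="V_linear_normal",
    )
    u = VectorField(
        fn=lambda p: np.asarray(p, float) @ K.T,
        dim=n,
        jac=lambda p: np.broadcast_to(K, np.asarray(p).shape + (n,)).copy(),
        div=lambda p: np.zeros(np.asarray(p).shape[:-1]),
        name="u_linear_normal",
    )
    F = VectorField(
        fn=lambda p: np.asarray(p, float) @ A.T,
        dim=n,
        jac=lambda p: np.broadcast_to(A, np.asarray(p).shape + (n,)).copy(),
        div=lambda p: np.full(np.asarray(p).shape[:-1], float(np.trace(A))),
        name="F=Ax",
    )
    return assemble_system(
        F=F, V=V, u=u, D=D, dim=n, name="linear_normal",
        params={"A": A.tolist(), "D": D},
    )


def from_potential_antisym(V: ScalarField, A_matrix, D: float) -> SystemSpec:
    """Perpendicular-HHD-by-construction class: u = A grad(V) with constant
    antisymmetric A.

    Antisymmetry makes grad(V) . A grad(V) = 0 identically, and
    div(A grad V) = sum_ij A_ij d_i d_j V = 0 because A is antisymmetric
    while the Hessian is symmetric.
    """
    A = np.asarray(A_matrix, dtype=float)
    if not np.array_equal(A, -A.T):
        raise ValueError("A_matrix must be exactly antisymmetric")
    if A.shape != (V.dim, V.dim):
        raise ValueError("A_matrix shape must match the potential dimension")

    u = VectorField(
        fn=lambda p: V.gradient(p) @ A.T,
        dim=V.dim,
        div=lambda p: np.zeros(np.asarray(p).shape[:-1]),
        provenance=V.provenance,
        name="u=A gradV",
    )
    return assemble_system(
        V=V, u=u, D=D, dim=V.dim, name="from_potential_antisym",
        params={"A": A.tolist(), "D": D}, domain=V.domain,
    )
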