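"""Scalar/vector field abstractions and the drift-diffusion system container.

Every other module consumes these types.  Fields evaluate vectorised on
arrays of points of shape ``(..., n)``; derivatives use supplied closed
forms when available and fall back to central finite differences
(second-order accurate) otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

__all__ = [
    "Box",
    "ScalarField",
    "VectorField",
    "SystemSpec",
    "evaluate_calculus",
    "assemble_system",
    "ConsistencyError",
    "DEFAULT_FD_STEP",
]

DEFAULT_FD_STEP = 1e-5

# combined abs/rel tolerances for closed-form consistency checks
ATOL_CLOSED = 1e-9
RTOL_CLOSED = 1e-6
RTOL_FD = 1e-4


class ConsistencyError(ValueError):
    """A declared decomposition does not reproduce the declared drift."""


@dataclass(frozen=True)
class Box:
    """Axis-aligned evaluation domain.  Evaluation outside is permitted but
    flagged by :meth:`contains` consumers."""

    lo: tuple
    hi: tuple

    def contains(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        lo = np.asarray(self.lo)
        hi = np.asarray(self.hi)
        return np.all((points >= lo) & (points <= hi), axis=-1)

    @property
    def dim(self) -> int:
        return len(self.lo)


def _as_points(points, dim: int) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.shape[-1] != dim:
        raise ValueError(
            f"points have dimension {pts.shape[-1]}, field has dimension {dim}"
        )
    return pts


@dataclass
class ScalarField:
    """A scalar function on R^n with optional closed-form derivatives.

    Parameters
    ----------
    fn
        Vectorised evaluator mapping ``(..., n)`` arrays to ``(...)`` values.
    grad, lap
        Optional closed-form gradient / Laplacian.  When absent, central
        finite differences with ``fd_step`` are used.
    provenance
        ``closed_form`` | ``finite_difference`` | ``grid_interpolated``.
    """

    fn: Callable[[np.ndarray], np.ndarray]
    dim: int
    grad: Optional[Callable[[np.ndarray], np.ndarray]] = None
    lap: Optional[Callable[[np.ndarray], np.ndarray]] = None
    provenance: str = "closed_form"
    domain: Optional[Box] = None
    fd_step: float = DEFAULT_FD_STEP
    name: str = ""

    def __call__(self, points) -> np.ndarray:
        return np.asarray(self.fn(_as_points(points, self.dim)), dtype=float)

    def gradient(self, points) -> np.ndarray:
        pts = _as_points(points, self.dim)
        if self.grad is not None:
            return np.asarray(self.grad(pts), dtype=float)
        return self._fd_gradient(pts)

    def laplacian(self, points) -> np.ndarray:
        pts = _as_points(points, self.dim)
        if self.lap is not None:
            return np.asarray(self.lap(pts), dtype=float)
        return self._fd_laplacian(pts)

    def _fd_gradient(self, pts: np.ndarray) -> np.ndarray:
        h = self.fd_step
        out = np.empty(pts.shape, dtype=float)
        for i in range(self.dim):
            e = np.zeros(self.dim)
            e[i] = h
            out[..., i] = (self.fn(pts + e) - self.fn(pts - e)) / (2.0 * h)
        return out

    def _fd_laplacian(self, pts: np.ndarray) -> np.ndarray:
        h = self.fd_step
        f0 = np.asarray(self.fn(pts), dtype=float)
        out = np.zeros(f0.shape, dtype=float)
        for i in range(self.dim):
            e = np.zeros(self.dim)
            e[i] = h
            out += (self.fn(pts + e) - 2.0 * f0 + self.fn(pts - e)) / h**2
        return out

    def shifted(self, offset: float) -> "ScalarField":
        """Same field minus a constant (derivatives unchanged)."""
        return ScalarField(
            fn=lambda p: self.fn(p) - offset,
            dim=self.dim,
            grad=self.grad,
            lap=self.lap,
            provenance=self.provenance,
            domain=self.domain,
            fd_step=self.fd_step,
            name=self.name,
        )


@dataclass
class VectorField:
    """A vector function on R^n with optional Jacobian / divergence."""

    fn: Callable[[np.ndarray], np.ndarray]
    dim: int
    jac: Optional[Callable[[np.ndarray], np.ndarray]] = None
    div: Optional[Callable[[np.ndarray], np.ndarray]] = None
    provenance: str = "closed_form"
    domain: Optional[Box] = None
    fd_step: float = DEFAULT_FD_STEP
    name: str = ""

    def __call__(self, points) -> np.ndarray:
        return np.asarray(self.fn(_as_points(points, self.dim)), dtype=float)

    def jacobian(self, points) -> np.ndarray:
        pts = _as_points(points, self.dim)
        if self.jac is not None:
            return np.asarray(self.jac(pts), dtype=float)
        h = self.fd_step
        out = np.empty(pts.shape + (self.dim,), dtype=float)
        for j in range(self.dim):
            e = np.zeros(self.dim)
            e[j] = h
            out[..., :, j] = (self.fn(pts + e) - self.fn(pts - e)) / (2.0 * h)
        return out

    def divergence(self, points) -> np.ndarray:
        pts = _as_points(points, self.dim)
        if self.div is not None:
            return np.asarray(self.div(pts), dtype=float)
        h = self.fd_step
        out = np.zeros(pts.shape[:-1], dtype=float)
        for i in range(self.dim):
            e = np.zeros(self.dim)
            e[i] = h
            out += (self.fn(pts + e)[..., i] - self.fn(pts - e)[..., i]) / (2.0 * h)
        return out


def evaluate_calculus(field, points, operator: str) -> np.ndarray:
    """Apply a differential operator to a field at the given points.

    ``gradient``/``laplacian`` require a :class:`ScalarField`;
    ``divergence``/``jacobian`` a :class:`VectorField`.  Closed forms are
    used when supplied, otherwise second-order central differences.
    """
    scalar_ops = {"gradient", "laplacian"}
    vector_ops = {"divergence", "jacobian"}
    if operator in scalar_ops:
        if not isinstance(field, ScalarField):
            raise TypeError(f"operator {operator!r} requires a ScalarField")
        return getattr(field, operator)(points)
    if operator in vector_ops:
        if not isinstance(field, VectorField):
            raise TypeError(f"operator {operator!r} requires a VectorField")
        return getattr(field, operator)(points)
    raise ValueError(f"unknown operator {operator!r}")


@dataclass
class SystemSpec:
    """An overdamped Langevin system dx/dt = F(x) + xi with <xi xi'> = 2D delta.

    The total drift F may optionally be declared as decomposed into a
    gradient part -grad(V), a solenoidal part u and a perturbation
    lambda*r, i.e. F = -grad(V) + u + lam*r.  The noise xi itself is
    realised by the simulator, never stored here.
    """

    dim: int
    D: float
    F: VectorField
    V: Optional[ScalarField] = None
    u: Optional[VectorField] = None
    r: Optional[VectorField] = None
    lam: float = 0.0
    name: str = ""
    params: dict = field(default_factory=dict)
    domain: Optional[Box] = None

    def __post_init__(self):
        if self.D < 0:
            raise ValueError(f"noise strength D must be non-negative, got {self.D}")

    @property
    def has_decomposition(self) -> bool:
        return self.V is not None and self.u is not None

    def drift_from_parts(self, points) -> np.ndarray:
        """-grad(V) + u + lam*r from the declared parts."""
        pts = _as_points(points, self.dim)
        out = np.zeros(pts.shape, dtype=float)
        if self.V is not None:
            out -= self.V.gradient(pts)
        if self.u is not None:
            out += self.u(pts)
        if self.r is not None:
            out += self.lam * self.r(pts)
        return out


def _synthesize_F(V, u, r, lam, dim, domain) -> VectorField:
    def fn(pts):
        out = np.zeros(np.asarray(pts, dtype=float).shape, dtype=float)
        if V is not None:
            out -= V.gradient(pts)
        if u is not None:
            out += u(pts)
        if r is not None:
            out += lam * r(pts)
        return out

    def div(pts):
        pts = np.asarray(pts, dtype=float)
        out = np.zeros(pts.shape[:-1], dtype=float)
        if V is not None:
            out -= V.laplacian(pts)
        if u is not None:
            out += u.divergence(pts)
        if r is not None:
            out += lam * r.divergence(pts)
        return out

    return VectorField(fn=fn, dim=dim, div=div, domain=domain, name="F(parts)")


def _consistency_points(dim: int, domain: Optional[Box], n_points: int, seed: int):
    rng = np.random.default_rng(seed)
    if domain is not None:
        lo = np.asarray(domain.lo, dtype=float)
        hi = np.asarray(domain.hi, dtype=float)
    else:
        lo, hi = -np.ones(dim), np.ones(dim)
    return rng.uniform(lo, hi, size=(n_points, dim))


def assemble_system(
    *,
    F: Optional[VectorField] = None,
    V: Optional[ScalarField] = None,
    u: Optional[VectorField] = None,
    r: Optional[VectorField] = None,
    lam: float = 0.0,
    D: float = 0.0,
    dim: Optional[int] = None,
    name: str = "",
    params: Optional[dict] = None,
    domain: Optional[Box] = None,
    check_points: int = 32,
    check_seed: int = 0,
) -> SystemSpec:
    """Build a :class:`SystemSpec` from a total drift and/or its parts.

    When parts are given and ``F`` is absent, the total drift is synthesized
    as F = -grad(V) + u + lam*r.  When both are given, agreement is checked
    at a seeded sample of points and a :class:`ConsistencyError` naming the
    worst point is raised on disagreement beyond tolerance.
    """
    parts_given = any(p is not None for p in (V, u, r))
    if F is None and not parts_given:
        raise ValueError("assemble_system needs F or at least one decomposition part")
    if dim is None:
        for f in (F, V, u, r):
            if f is not None:
                dim = f.dim
                break
    for f in (F, V, u, r):
        if f is not None and f.dim != dim:
            raise ValueError("mismatched field dimensions")

    if F is None:
        F = _synthesize_F(V, u, r, lam, dim, domain)
    elif parts_given:
        pts = _consistency_points(dim, domain, check_points, check_seed)
        trial = SystemSpec(dim=dim, D=D, F=F, V=V, u=u, r=r, lam=lam, domain=domain)
        got = F(pts)
        want = trial.drift_from_parts(pts)
        fd_involved = any(
            f is not None and f.provenance != "closed_form" for f in (V, u, r, F)
        )
        rtol = RTOL_FD if fd_involved else RTOL_CLOSED
        err = np.linalg.norm(got - want, axis=-1)
        scale = np.maximum(np.linalg.norm(want, axis=-1), 1.0)
        bad = err > ATOL_CLOSED + rtol * scale
        if np.any(bad):
            i = int(np.argmax(err / scale))
            raise ConsistencyError(
                f"declared parts disagree with F: |F - (-gradV+u+lam*r)| = "
                f"{err[i]:.3e} at point {pts[i].tolist()}"
            )

    return SystemSpec(
        dim=dim,
        D=D,
        F=F,
        V=V,
        u=u,
        r=r,
        lam=lam,
        name=name,
        params=dict(params or {}),
        domain=domain,
    )
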