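"""Perturbative stationary measures of near-perpendicular-HHD systems.

For a drift with a perpendicular Helmholtz-Hodge decomposition the
stationary measure is the Boltzmann form P ~ exp(-V/D) regardless of the
solenoidal part.  A small perturbation lam*r corrects the Cole-Hopf
potential at first order: P ~ exp(-(V + lam*W_r)/D) with W_r obtained by a
line integral of r . grad(V) along the auxiliary ascent flow
dy/dt = grad(V) + u.

Sign convention
---------------
W_r is defined so that the stationary Fokker-Planck residual of
exp(-(V + lam*W_r)/D) is o(lam) in the small-noise regime, i.e. W_r
solves (grad V + u) . grad W_r = - r . grad V.  Along the *ascent* flow,
W_r therefore accumulates -int r.gradV dt; numerically we integrate the
attracting *descent* flow -(grad V + u) from each query point down to the
base region and negate the accumulated integral.  This convention is
pinned by two independent oracles in the test suite (symbolic FP residual
and the exact Gaussian stationary covariance of the linear testbed);
for the linear example with u = (Omega*y, -Omega*x) and r = (y, 0) it
gives W_r = -[2xy + Omega(x^2 - y^2)] / (4 (1 + Omega^2)).

The O(D^0) correction to the first-order Cole-Hopf potential is not
modelled: the machinery targets the leading small-D form.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np
from scipy.integrate import solve_ivp
from scipy.interpolate import RegularGridInterpolator

from .fields import Box, ScalarField, SystemSpec
from .hhd import SampleSpec, check_orthogonal_hhd

__all__ = [
    "PotentialModel",
    "boltzmann_potential",
    "descent_line_integral",
    "compute_Wr",
    "wr_on_grid",
    "wr_scalar_field",
    "effective_potential",
    "fp_residual",
]


@dataclass
class PotentialModel:
    """A Cole-Hopf potential H with P_stat ~ exp(-H).

    ``kind`` records provenance: ``analytic`` (closed-form Boltzmann),
    ``perturbative`` (first-order corrected) or ``empirical`` (from a
    simulated density grid).  ``H`` is dimensionless; the additive offset
    is a free convention recorded in ``offset``.  ``valid`` masks the
    region where H (and its derivatives) may be evaluated.
    """

    kind: str
    H: ScalarField
    D: float
    lam: float = 0.0
    source: str = ""
    offset: str = "reference_point"
    mask: Optional[Callable[[np.ndarray], np.ndarray]] = None
    metadata: dict = field(default_factory=dict)

    @property
    def dim(self) -> int:
        return self.H.dim

    def __call__(self, points) -> np.ndarray:
        return self.H(points)

    def gradient(self, points) -> np.ndarray:
        return self.H.gradient(points)

    def laplacian(self, points) -> np.ndarray:
        return self.H.laplacian(points)

    def valid(self, points) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        if self.mask is not None:
            return np.asarray(self.mask(pts), dtype=bool)
        if self.H.domain is not None:
            return self.H.domain.contains(pts)
        return np.ones(pts.shape[:-1], dtype=bool)

    def check_integrable(self, bounds=None, shape=None) -> bool:
        """Numerically check that exp(-H) has finite mass on the validity
        region (trapezoidal quadrature on a grid)."""
        if bounds is None:
            box = self.H.domain or Box((-3.0,) * self.dim, (3.0,) * self.dim)
            bounds = tuple(zip(box.lo, box.hi))
        if shape is None:
            shape = (64,) * self.dim
        axes = [np.linspace(lo, hi, m) for (lo, hi), m in zip(bounds, shape)]
        mesh = np.meshgrid(*axes, indexing="ij")
        pts = np.stack(mesh, axis=-1)
        vals = np.where(self.valid(pts), np.exp(-self.H(pts)), 0.0)
        mass = vals
        for ax, grid in enumerate(axes):
            mass = np.trapezoid(mass, grid, axis=0)
        return bool(np.isfinite(mass) and mass > 0)


def boltzmann_potential(system: SystemSpec, force: bool = False,
                        sample: Optional[SampleSpec] = None) -> PotentialModel:
    """Zeroth-order Cole-Hopf potential H = V/D for a perpendicular-HHD
    system.

    Refuses systems without a verified decomposition (the Boltzmann form
    is only stationary when div u = 0 and u . grad V = 0) unless ``force``
    is set, which is then recorded in the metadata.
    """
    if system.V is None:
        raise ValueError("system declares no potential V")
    if system.D <= 0:
        raise ValueError(
            "boltzmann_potential needs D > 0; the deterministic limit is "
            "handled by typical.omega_limit_descent"
        )
    meta = {}
    if system.u is not None:
        report = check_orthogonal_hhd(system, sample=sample)
        if not report.is_orthogonal_hhd and not force:
            raise ValueError(
                "declared decomposition fails the orthogonality check "
                f"(norm residuals div={report.norm_div_u:.3g}, "
                f"orth={report.norm_u_dot_gradV:.3g}); pass force=True to override"
            )
        meta["hhd_check"] = report.to_dict()
    meta["forced"] = bool(force)

    D = float(system.D)
    V = system.V
    H = ScalarField(
        fn=lambda p: V.fn(p) / D,
        dim=V.dim,
        grad=(lambda p: V.grad(p) / D) if V.grad is not None else None,
        lap=(lambda p: V.lap(p) / D) if V.lap is not None else None,
        provenance=V.provenance,
        domain=V.domain or system.domain,
        name="V/D",
    )
    return PotentialModel(kind="analytic", H=H, D=D, lam=0.0,
                          source="boltzmann", metadata=meta)


@dataclass
class WrResult:
    values: np.ndarray          # W_r at the query points (W_r(base) = 0)
    converged: np.ndarray       # bool per point
    t_used: np.ndarray          # descent time to reach the base region
    base_point: np.ndarray


def _require_parts(system: SystemSpec):
    if system.V is None or system.u is None or system.r is None:
        raise ValueError("compute_Wr needs declared V, u and r")


def descent_line_integral(
    ascent_flow,
    source,
    base_point,
    query_points,
    *,
    t_max: float = 200.0,
    rtol: float = 1e-7,
    atol: float = 1e-9,
    base_radius: float = 1e-6,
    speed_floor: float = 1e-8,
) -> WrResult:
    """Solve the directional-derivative problem (ascent_flow . grad f) = source
    by characteristics, normalising f(base) = 0.

    From each query point the descent flow dx/dt = -ascent_flow(x) is
    integrated towards the base region while accumulating
    int source(x(s)) ds; since the source is invariant under the time
    re-parametrisation, f(query) = accumulated integral.  Points whose
    descent does not reach the base region within ``t_max``, or that
    stall at a spurious fixed point of the flow, come back flagged
    ``converged=False``.
    """
    base = np.asarray(base_point, dtype=float)
    queries = np.atleast_2d(np.asarray(query_points, dtype=float))

    def rhs(t, z):
        x = z[:-1]
        return np.append(-np.asarray(ascent_flow(x), dtype=float),
                         float(source(x)))

    def reach_base(t, z):
        return float(np.linalg.norm(z[:-1] - base)) - base_radius

    reach_base.terminal = True
    reach_base.direction = -1

    def stalled(t, z):
        return float(np.linalg.norm(ascent_flow(z[:-1]))) - speed_floor

    stalled.terminal = True
    stalled.direction = -1

    values = np.empty(len(queries))
    conv = np.zeros(len(queries), dtype=bool)
    t_used = np.full(len(queries), np.nan)
    for k, q in enumerate(queries):
        if np.linalg.norm(q - base) <= base_radius:
            values[k], conv[k], t_used[k] = 0.0, True, 0.0
            continue
        sol = solve_ivp(
            rhs, (0.0, t_max), np.append(q, 0.0), method="RK45",
            rtol=rtol, atol=atol, events=(reach_base, stalled),
        )
        values[k] = float(sol.y[-1, -1])
        reached = len(sol.t_events[0]) > 0
        # stalling inside the base region still counts as arrival
        near = float(np.linalg.norm(sol.y[:-1, -1] - base)) < 1e3 * base_radius
        conv[k] = bool(reached or near)
        t_used[k] = float(sol.t[-1])
    return WrResult(values=values, converged=conv, t_used=t_used, base_point=base)


def compute_Wr(system: SystemSpec, base_point, query_points, **kwargs) -> WrResult:
    """First-order stationary-measure correction W_r at the query points.

    W_r solves (grad V + u) . grad W_r = - r . grad V (see the module
    docstring for the sign arbitration) and is evaluated by the descent
    line integral along the attracting flow -(grad V + u), with
    W_r(base) = 0 by convention; all downstream comparisons are
    offset-invariant.
    """
    _require_parts(system)
    base = np.asarray(base_point, dtype=float)
    gnorm = float(np.linalg.norm(system.V.gradient(base)))
    if gnorm > 1e-6:
        raise ValueError(
            f"base point {base.tolist()} is not near an attractor of the "
            f"descent flow (|gradV| = {gnorm:.3g})"
        )
    V, u, r = system.V, system.u, system.r
    return descent_line_integral(
        lambda x: V.gradient(x) + u(x),
        lambda x: -float(np.dot(r(x), V.gradient(x))),
        base, query_points, **kwargs)


def wr_on_grid(system: SystemSpec, base_point, bounds, shape, **kwargs):
    """Tabulate W_r on a regular grid; returns (axes, values, converged)."""
    axes = [np.linspace(lo, hi, m) for (lo, hi), m in zip(bounds, shape)]
    mesh = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([m.ravel() for m in mesh], axis=-1)
    res = compute_Wr(system, base_point, pts, **kwargs)
    grid_shape = tuple(shape)
    return axes, res.values.reshape(grid_shape), res.converged.reshape(grid_shape)


def wr_scalar_field(axes, values, fd_step: Optional[float] = None) -> ScalarField:
    """Wrap a tabulated W_r grid as an interpolated scalar field (cubic
    where possible), for use in :func:`effective_potential`."""
    method = "cubic" if all(len(a) >= 4 for a in axes) else "linear"
    rgi = RegularGridInterpolator(tuple(axes), values, method=method,
                                  bounds_error=False, fill_value=np.nan)
    ndim = len(axes)

    def interp(p):
        p = np.asarray(p, dtype=float)
        return np.asarray(rgi(p.reshape(-1, ndim))).reshape(p.shape[:-1])

    lo = tuple(float(a[0]) for a in axes)
    hi = tuple(float(a[-1]) for a in axes)
    step = fd_step or max(float(a[1] - a[0]) for a in axes)
    return ScalarField(
        fn=interp,
        dim=len(axes),
        provenance="grid_interpolated",
        domain=Box(lo, hi),
        fd_step=step,
        name="W_r(grid)",
    )


def effective_potential(system: SystemSpec,
                        wr: Union[ScalarField, PotentialModel]) -> PotentialModel:
    """First-order corrected Cole-Hopf potential H = (V + lam*W_r)/D."""
    if system.V is None:
        raise ValueError("system declares no potential V")
    if system.D <= 0:
        raise ValueError("effective_potential needs D > 0")
    W = wr.H if isinstance(wr, PotentialModel) else wr
    if W.dim != system.dim:
        raise ValueError("W_r field dimension does not match the system")
    V, lam, D = system.V, float(system.lam), float(system.D)

    grad = None
    if V.grad is not None:
        grad = lambda p: (V.grad(p) + lam * W.gradient(p)) / D
    lap = None
    if V.lap is not None and W.lap is not None:
        lap = lambda p: (V.lap(p) + lam * W.lap(p)) / D

    H = ScalarField(
        fn=lambda p: (V.fn(p) + lam * W(p)) / D,
        dim=V.dim,
        grad=grad,
        lap=lap,
        provenance=("closed_form" if W.provenance == "closed_form"
                    and V.provenance == "closed_form" else W.provenance),
        domain=W.domain or V.domain,
        fd_step=W.fd_step,
        name="(V+lam*Wr)/D",
    )
    mask = (lambda p: W.domain.contains(p)) if W.domain is not None else None
    return PotentialModel(kind="perturbative", H=H, D=D, lam=lam,
                          source="effective_potential",
                          mask=mask,
                          metadata={"lambda": lam, "D": D})


def fp_residual(system: SystemSpec, pot: PotentialModel, points) -> np.ndarray:
    """Stationarity residual of P ~ exp(-H) under the Fokker-Planck operator.

    Returns the per-point scalar

        -div F + F . grad H + D [ (grad H)^2 - Lap H ]

    which is the stationary FP operator applied to exp(-H), divided by
    exp(-H); it vanishes identically iff exp(-H) is stationary.  Points
    outside the potential's validity mask are returned as NaN.
    """
    if system.D <= 0:
        raise ValueError("fp_residual needs D > 0")
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    gH = pot.gradient(pts)
    lapH = pot.laplacian(pts)
    Fv = system.F(pts)
    divF = system.F.divergence(pts)
    res = (-divF + np.einsum("...i,...i->...", Fv, gH)
           + system.D * (np.einsum("...i,...i->...", gH, gH) - lapH))
    ok = pot.valid(pts)
    return np.where(ok, res, np.nan)
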