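"""Typical trajectories and along-path diagnostics.

A typical trajectory is the deterministic path dX/dt = F + D grad(H)
(drift plus osmotic velocity) built from a Cole-Hopf potential H of the
stationary measure.  Its Liouville dynamics leaves the stationary density
invariant, but pointwise the stationary probability is *not* conserved
along the path unless the drift has a perpendicular HHD: the local rate
is d(rho)/dt = -rho (D Lap H + div F), and the same quantity with
opposite sign is the stochastic entropy production dH/dt = -div(Xdot).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.integrate import solve_ivp

from .fields import SystemSpec
from .stationary import PotentialModel

__all__ = [
    "TypicalTrajectory",
    "typical_trajectory",
    "probability_rate",
    "entropy_production_rate",
    "near_hhd_rate",
    "omega_limit_descent",
    "first_return_period",
]


@dataclass
class TypicalTrajectory:
    t: np.ndarray
    X: np.ndarray                 # (n_t, dim)
    Xdot: np.ndarray              # (n_t, dim)
    H: np.ndarray
    P: np.ndarray                 # exp(-H), unnormalized
    dPdt_eq_form: np.ndarray      # -P (D LapH + divF)
    dPdt_chain: np.ndarray        # (F + D gradH).(-gradH) P
    Hdot: np.ndarray              # -(divF + D LapH)
    divF: np.ndarray
    V: Optional[np.ndarray] = None
    stalled: bool = False
    meta: dict = field(default_factory=dict)


def _typical_rhs(system: SystemSpec, pot: PotentialModel):
    D = system.D

    def rhs(t, x):
        return system.F(x) + D * pot.gradient(x)

    return rhs


def typical_trajectory(
    system: SystemSpec,
    pot: PotentialModel,
    x0,
    t_span,
    n_eval: int = 1000,
    rtol: float = 1e-7,
    atol: float = 1e-9,
    speed_floor: float = 1e-10,
    max_step: float = np.inf,
) -> TypicalTrajectory:
    """Integrate dX/dt = F + D grad(H) and attach along-path diagnostics.

    Raises if the path exits the potential's validity mask (naming the
    exit point); termination at a stationary point of the typical flow is
    reported via the ``stalled`` flag.
    """
    if system.D <= 0:
        raise ValueError("typical trajectories need D > 0")
    x0 = np.asarray(x0, dtype=float)
    if not bool(np.atleast_1d(pot.valid(x0))[0]):
        raise ValueError(f"initial point {x0.tolist()} outside potential mask")
    rhs = _typical_rhs(system, pot)

    def exit_mask(t, x):
        return 1.0 if bool(np.atleast_1d(pot.valid(x))[0]) else -1.0

    exit_mask.terminal = True

    def stalled_ev(t, x):
        return float(np.linalg.norm(rhs(t, x))) - speed_floor

    stalled_ev.terminal = True
    stalled_ev.direction = -1

    t_eval = np.linspace(t_span[0], t_span[1], n_eval)
    sol = solve_ivp(rhs, t_span, x0, method="RK45", rtol=rtol, atol=atol,
                    t_eval=t_eval, events=(exit_mask, stalled_ev),
                    max_step=max_step, dense_output=False)
    if len(sol.t_events[0]) > 0:
        raise ValueError(
            f"typical trajectory exits the potential mask at "
            f"{sol.y_events[0][0].tolist()} (t = {sol.t_events[0][0]:.4g})"
        )
    stalled = len(sol.t_events[1]) > 0
    t = sol.t
    X = sol.y.T
    return _attach_diagnostics(system, pot, t, X, stalled=stalled,
                               meta={"rtol": rtol, "atol": atol,
                                     "h_source": pot.kind})


def _attach_diagnostics(system, pot, t, X, stalled=False, meta=None):
    D = system.D
    gH = pot.gradient(X)
    Xdot = system.F(X) + D * gH
    H = pot(X)
    P = np.exp(-H)
    eq_form, chain = probability_rate(system, pot, X)
    lapH = pot.laplacian(X)
    divF = system.F.divergence(X)
    Hdot = -(divF + D * lapH)
    V = system.V(X) if system.V is not None else None
    return TypicalTrajectory(
        t=t, X=X, Xdot=Xdot, H=H, P=P,
        dPdt_eq_form=eq_form, dPdt_chain=chain,
        Hdot=Hdot, divF=divF, V=V, stalled=stalled, meta=dict(meta or {}),
    )


def probability_rate(system: SystemSpec, pot: PotentialModel, states):
    """Pointwise rate of change of the stationary density along the
    typical flow, in two forms:

    * the divergence form  -rho (D Lap H + div F)
    * the chain rule       (F + D grad H) . (-grad H) rho

    with rho = exp(-H) unnormalized.  The two coincide exactly iff
    exp(-H) is stationary; their discrepancy is itself a stationarity
    diagnostic of the supplied H.  Entries whose second derivatives are
    unavailable inside the mask evaluate to NaN.
    """
    pts = np.atleast_2d(np.asarray(states, dtype=float))
    H = pot(pts)
    rho = np.exp(-H)
    gH = pot.gradient(pts)
    lapH = pot.laplacian(pts)
    divF = system.F.divergence(pts)
    Fv = system.F(pts)
    eq_form = -rho * (system.D * lapH + divF)
    chain = -rho * np.einsum("...i,...i->...", Fv + system.D * gH, gH)
    return eq_form, chain


@dataclass
class EntropyRate:
    value: np.ndarray             # exact -(div F + D Lap H)
    reference: Optional[np.ndarray] = None  # -lam div r, when parts declared


def entropy_production_rate(system: SystemSpec, pot: PotentialModel,
                            states) -> EntropyRate:
    """Stochastic entropy production rate dH/dt = -div(Xdot) along the
    typical flow.

    Always reports the exact -(div F + D Lap H); for systems with
    declared parts the first-order reference -lam div(r) is attached for
    comparison (the Lap(W_r) term it omits vanishes only when W_r is
    harmonic, so the two generally differ at O(lam)).
    """
    pts = np.atleast_2d(np.asarray(states, dtype=float))
    lapH = pot.laplacian(pts)
    divF = system.F.divergence(pts)
    value = -(divF + system.D * lapH)
    ref = None
    if system.r is not None:
        ref = -system.lam * system.r.divergence(pts)
    return EntropyRate(value=value, reference=ref)


def near_hhd_rate(system: SystemSpec, wr, states) -> np.ndarray:
    """Leading-order activity gauge for the probability rate along the
    near-HHD typical trajectory: -(2 lam / D) (r . grad V) P_stat with
    P_stat ~ exp(-(V + lam W_r)/D) unnormalized.

    Note: with the sign-corrected W_r used throughout this package, the
    actual rate along the corrected typical trajectory is O(lam^2) -- the
    O(lam) activity contribution cancels; this closed form quantifies the
    magnitude of that cancelled contribution and hence the distance to a
    perpendicular HHD.  See the methods note.
    """
    if system.V is None or system.u is None or system.r is None:
        raise ValueError("near_hhd_rate needs declared V, u and r")
    if system.D <= 0:
        raise ValueError("near_hhd_rate needs D > 0")
    from .stationary import effective_potential

    W = wr.H if isinstance(wr, PotentialModel) else wr
    pot = effective_potential(system, W)
    pts = np.atleast_2d(np.asarray(states, dtype=float))
    P = np.exp(-pot(pts))
    rdotg = np.einsum("...i,...i->...", system.r(pts), system.V.gradient(pts))
    return -(2.0 * system.lam / system.D) * rdotg * P


@dataclass
class DescentResult:
    terminal: np.ndarray
    grad_norm: float
    converged: bool
    t_used: float


def omega_limit_descent(system: SystemSpec, x0, t_max: float = 1000.0,
                        tol: float = 1e-6, bound: float = 1e6) -> DescentResult:
    """Deterministic flow dx/dt = F until |grad V| < tol.

    For drifts with a perpendicular HHD the omega-limit set lies on
    grad V = 0, so the descent terminates there even in the presence of a
    persistent solenoidal rotation.  Divergence beyond ``bound`` returns a
    non-converged result.
    """
    if system.V is None:
        raise ValueError("omega_limit_descent needs a declared potential V")
    x0 = np.asarray(x0, dtype=float)

    def rhs(t, x):
        return system.F(x)

    def small_grad(t, x):
        # trigger slightly inside the target so the terminal state
        # strictly satisfies |gradV| < tol despite root-finding slop
        return float(np.linalg.norm(system.V.gradient(x))) - 0.9 * tol

    small_grad.terminal = True
    small_grad.direction = -1

    def diverged(t, x):
        return bound - float(np.linalg.norm(x))

    diverged.terminal = True
    diverged.direction = -1

    if float(np.linalg.norm(system.V.gradient(x0))) < tol:
        return DescentResult(terminal=x0, grad_norm=float(
            np.linalg.norm(system.V.gradient(x0))), converged=True, t_used=0.0)
    sol = solve_ivp(rhs, (0.0, t_max), x0, method="RK45", rtol=1e-8,
                    atol=1e-10, events=(small_grad, diverged))
    xT = sol.y[:, -1]
    gnorm = float(np.linalg.norm(system.V.gradient(xT)))
    converged = len(sol.t_events[0]) > 0 or gnorm < tol
    return DescentResult(terminal=xT, grad_norm=gnorm, converged=converged,
                         t_used=float(sol.t[-1]))


def first_return_period(system: SystemSpec, pot: PotentialModel, x0,
                        t_max: float = 50.0, t_min: float = 0.5,
                        capture: float = 0.5, rtol: float = 1e-7,
                        atol: float = 1e-9):
    """Poincare first-return time of the typical flow.

    The section is the hyperplane through ``x0`` normal to the initial
    typical velocity; the first crossing in the initial direction after
    ``t_min`` and within distance ``capture`` of ``x0`` defines one orbit
    period.  Returns ``(period, trajectory)`` where the trajectory spans
    exactly one period.  Raises if no return is found within ``t_max``.
    """
    x0 = np.asarray(x0, dtype=float)
    rhs = _typical_rhs(system, pot)
    v0 = np.asarray(rhs(0.0, x0), dtype=float)
    speed = np.linalg.norm(v0)
    if speed < 1e-12:
        raise ValueError("typical flow is stationary at x0; no orbit")
    n_hat = v0 / speed

    def section(t, x):
        return float(np.dot(x - x0, n_hat))

    section.direction = 1

    # solve once, collect section crossings via the event machinery
    sol = solve_ivp(rhs, (0.0, t_max), x0, method="RK45", rtol=rtol,
                    atol=atol, events=(section,), dense_output=True)
    period = None
    for t_ev, x_ev in zip(sol.t_events[0], sol.y_events[0]):
        if t_ev > t_min and np.linalg.norm(x_ev - x0) < capture:
            period = float(t_ev)
            break
    if period is None:
        raise RuntimeError(
            f"no Poincare return within t_max={t_max} (crossings at "
            f"{sol.t_events[0].tolist()})"
        )
    t = np.linspace(0.0, period, 1024)
    X = sol.sol(t).T
    traj = _attach_diagnostics(system, pot, t, X,
                               meta={"period": period, "h_source": pot.kind})
    return period, traj
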