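"""Verification of orthogonal Helmholtz-Hodge decompositions.

A declared decomposition F = -grad(V) + u (+ lam*r) is a *perpendicular*
HHD when u is solenoidal (div u = 0) and everywhere orthogonal to the
gradient flow (u . grad V = 0).  This module quantifies the deviation of a
declared decomposition from that structure; it does not construct
decompositions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .fields import SystemSpec

__all__ = ["SampleSpec", "DecompositionReport", "check_orthogonal_hhd", "activity_gauge"]

TOL_CLOSED = 1e-8   # normalized verdict tolerance, closed-form derivatives
TOL_FD = 1e-4       # noise floor of central differences


@dataclass(frozen=True)
class SampleSpec:
    """Evaluation sample: a regular grid over ``bounds`` plus optional
    seeded uniform random points (both recorded for reproducibility)."""

    bounds: Sequence[tuple]            # ((lo, hi), ...) per axis
    shape: Sequence[int] = (101, 101)
    n_random: int = 0
    seed: int = 0

    def points(self) -> np.ndarray:
        axes = [np.linspace(lo, hi, num) for (lo, hi), num in zip(self.bounds, self.shape)]
        mesh = np.meshgrid(*axes, indexing="ij")
        pts = np.stack([m.ravel() for m in mesh], axis=-1)
        if self.n_random:
            rng = np.random.default_rng(self.seed)
            lo = np.array([b[0] for b in self.bounds])
            hi = np.array([b[1] for b in self.bounds])
            pts = np.concatenate([pts, rng.uniform(lo, hi, (self.n_random, len(self.bounds)))])
        return pts

    @classmethod
    def for_system(cls, system: SystemSpec, shape=(101, 101), n_random=0, seed=0):
        if system.domain is not None:
            bounds = tuple(zip(system.domain.lo, system.domain.hi))
        else:
            bounds = tuple((-2.0, 2.0) for _ in range(system.dim))
        return cls(bounds=bounds, shape=shape, n_random=n_random, seed=seed)


@dataclass
class DecompositionReport:
    max_div_u: float
    max_u_dot_gradV: float
    norm_div_u: float            # max|div u| / max|u| over sample
    norm_u_dot_gradV: float      # max|u.gradV| / (max|u| max|gradV|)
    solenoidal: bool
    orthogonal: bool
    is_orthogonal_hhd: bool
    tol: float
    worst_div_point: list
    worst_orth_point: list
    sample: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def check_orthogonal_hhd(
    system: SystemSpec,
    sample: Optional[SampleSpec] = None,
    tol: Optional[float] = None,
) -> DecompositionReport:
    """Evaluate |div u| and |u . grad V| on the sample and issue verdicts.

    Verdicts use residuals normalized by the field magnitudes on the
    sample, so they are scale-invariant; the tolerance defaults to the
    closed-form floor (1e-8) or the finite-difference floor (1e-4) as
    appropriate.
    """
    if system.V is None or system.u is None:
        raise ValueError(
            "system declares no decomposition parts; declare V and u "
            "(e.g. via assemble_system) before checking for a perpendicular HHD"
        )
    if sample is None:
        sample = SampleSpec.for_system(system)
    if tol is None:
        fd = (system.u.div is None or system.V.grad is None)
        tol = TOL_FD if fd else TOL_CLOSED

    pts = sample.points()
    div_u = system.u.divergence(pts)
    gradV = system.V.gradient(pts)
    u_vals = system.u(pts)
    dot = np.einsum("...i,...i->...", u_vals, gradV)

    umax = float(np.max(np.linalg.norm(u_vals, axis=-1)))
    gmax = float(np.max(np.linalg.norm(gradV, axis=-1)))
    max_div = float(np.max(np.abs(div_u)))
    max_dot = float(np.max(np.abs(dot)))
    norm_div = max_div / umax if umax > 0 else 0.0
    norm_dot = max_dot / (umax * gmax) if umax * gmax > 0 else 0.0

    solenoidal = norm_div < tol
    orthogonal = norm_dot < tol
    return DecompositionReport(
        max_div_u=max_div,
        max_u_dot_gradV=max_dot,
        norm_div_u=norm_div,
        norm_u_dot_gradV=norm_dot,
        solenoidal=solenoidal,
        orthogonal=orthogonal,
        is_orthogonal_hhd=bool(solenoidal and orthogonal),
        tol=float(tol),
        worst_div_point=pts[int(np.argmax(np.abs(div_u)))].tolist(),
        worst_orth_point=pts[int(np.argmax(np.abs(dot)))].tolist(),
        sample={
            "bounds": [list(b) for b in sample.bounds],
            "shape": list(sample.shape),
            "n_random": sample.n_random,
            "seed": sample.seed,
        },
    )


def activity_gauge(system: SystemSpec, sample: Optional[SampleSpec] = None) -> dict:
    """Gauge the 'non-trivial' activity of a declared perturbation.

    The perturbation strength lam measures the distance to a perpendicular
    HHD; this returns summary statistics of |r . grad V| (the component of
    the perturbation that actually feeds the stationary-measure correction)
    and of lam*|r| over the sample.
    """
    if system.r is None:
        raise ValueError("system declares no perturbation r")
    if system.V is None:
        raise ValueError("activity gauge needs a declared potential V")
    if sample is None:
        sample = SampleSpec.for_system(system)
    pts = sample.points()
    r_vals = system.r(pts)
    gradV = system.V.gradient(pts)
    rdot = np.abs(system.lam * np.einsum("...i,...i->...", r_vals, gradV))
    rmag = np.abs(system.lam) * np.linalg.norm(r_vals, axis=-1)
    return {
        "lambda": system.lam,
        "mean_abs_r_dot_gradV": float(np.mean(rdot)),
        "max_abs_r_dot_gradV": float(np.max(rdot)),
        "mean_lambda_r": float(np.mean(rmag)),
        "max_lambda_r": float(np.max(rmag)),
    }
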