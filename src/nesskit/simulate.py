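"""Seeded Euler-Maruyama ensemble simulation and the empirical Cole-Hopf
landscape.

The noise is additive with constant strength, so the Ito, Stratonovich and
Hanggi-Klimontovich readings of the Langevin equation coincide and only
the Euler-Maruyama scheme is provided.

Reproducibility: every walker owns a counter-based Philox stream keyed by
``(master_seed, walker_index)``, so results are bit-identical for a fixed
seed and do not reshuffle when the walker count or the chunking changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np
from scipy import ndimage
from scipy.interpolate import RegularGridInterpolator

from .fields import Box, ScalarField, SystemSpec
from .stationary import PotentialModel

__all__ = [
    "EnsembleTrajectory",
    "DensityGrid",
    "simulate_langevin",
    "simulate_density",
    "estimate_density",
    "cole_hopf",
]

_CHUNK = 512  # walkers per vectorised chunk


class BlowUpError(RuntimeError):
    pass


@dataclass
class EnsembleTrajectory:
    times: np.ndarray                 # recorded instants, shape (n_rec,)
    states: np.ndarray                # (walkers, n_rec, dim)
    dt: float
    seed: int
    burn_in: int                      # steps discarded before recording
    record_stride: int
    scheme: str = "euler_maruyama"
    system_meta: dict = field(default_factory=dict)

    @property
    def walkers(self) -> int:
        return self.states.shape[0]

    @property
    def dim(self) -> int:
        return self.states.shape[2]

    def samples(self) -> np.ndarray:
        """All recorded states flattened to (walkers * n_rec, dim)."""
        return self.states.reshape(-1, self.dim)


def _walker_rng(seed: int, walker: int) -> np.random.Generator:
    return np.random.Generator(
        np.random.Philox(np.random.SeedSequence(entropy=(int(seed), int(walker))))
    )


def _resolve_burn_in(burn_in, steps: int) -> int:
    if burn_in is None:
        return int(0.2 * steps)
    if isinstance(burn_in, float) and 0 <= burn_in < 1:
        return int(burn_in * steps)
    return int(burn_in)


def _run_ensemble(system, walkers, steps, dt, seed, init, burn_in,
                  record_stride, consume):
    """Core chunked Euler-Maruyama loop.

    ``consume(w0, states_chunk)`` is called per walker chunk with the
    recorded states array of shape (chunk, n_rec, dim); both the stored
    and the streaming-histogram front ends share this kernel, so they are
    bit-identical by construction.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if walkers < 1 or steps < 1:
        raise ValueError("walkers and steps must be >= 1")
    n = system.dim
    sigma = np.sqrt(2.0 * system.D * dt)
    rec_idx = np.arange(burn_in, steps, record_stride)
    n_rec = len(rec_idx)
    if n_rec == 0:
        raise ValueError("burn-in discards every step; nothing to record")
    rec_flag = np.zeros(steps, dtype=bool)
    rec_flag[rec_idx] = True

    t_block = 5000  # draw noise in time blocks to bound peak memory
    for w0 in range(0, walkers, _CHUNK):
        w1 = min(w0 + _CHUNK, walkers)
        c = w1 - w0
        x = np.empty((c, n))
        rngs = []
        for j, w in enumerate(range(w0, w1)):
            rng = _walker_rng(seed, w)
            if callable(init):
                x[j] = np.asarray(init(rng), dtype=float)
            else:
                x[j] = np.asarray(init, dtype=float)
            rngs.append(rng)
        out = np.empty((c, n_rec, n), dtype=np.float32)
        k = 0
        for s0 in range(0, steps, t_block):
            s1 = min(s0 + t_block, steps)
            noise = np.empty((c, s1 - s0, n))
            for j, rng in enumerate(rngs):
                noise[j] = rng.standard_normal((s1 - s0, n))
            for s in range(s0, s1):
                x += system.F(x) * dt + sigma * noise[:, s - s0, :]
                if not np.all(np.isfinite(x)):
                    bad = np.argwhere(~np.isfinite(x))[0]
                    raise BlowUpError(
                        f"non-finite state: walker {w0 + bad[0]}, step {s}, "
                        f"state {x[bad[0]].tolist()}"
                    )
                if rec_flag[s]:
                    out[:, k, :] = x
                    k += 1
        consume(w0, out)
    return rec_idx


def simulate_langevin(
    system: SystemSpec,
    walkers: int,
    steps: int,
    dt: float,
    seed: int,
    init: Union[Sequence[float], Callable],
    record_stride: int = 1,
    burn_in: Union[int, float, None] = 0,
) -> EnsembleTrajectory:
    """Euler-Maruyama ensemble: x <- x + F(x) dt + sqrt(2 D dt) N(0,1).

    ``init`` is either a point (all walkers start there) or a callable
    ``init(rng) -> point`` drawn once per walker from that walker's own
    stream.  Recorded states are float32 (storage); the integration is
    float64 throughout.
    """
    bi = _resolve_burn_in(burn_in, steps)
    states = np.empty(
        (walkers, len(np.arange(bi, steps, record_stride)), system.dim),
        dtype=np.float32,
    )

    def consume(w0, chunk):
        states[w0:w0 + chunk.shape[0]] = chunk

    rec_idx = _run_ensemble(system, walkers, steps, dt, seed, init, bi,
                            record_stride, consume)
    return EnsembleTrajectory(
        times=(rec_idx + 1) * dt,
        states=states,
        dt=dt,
        seed=seed,
        burn_in=bi,
        record_stride=record_stride,
        system_meta={"name": system.name, "params": system.params, "D": system.D},
    )


@dataclass
class DensityGrid:
    """Regular-grid stationary probability masses.

    Bins are half-open [lo, hi); masses are normalized over occupied
    (in-box) bins; ``h`` (set by :func:`cole_hopf`) is -log(mass) offset
    so that its minimum over the mask is zero.
    """

    edges: list                       # per-axis bin edges
    masses: np.ndarray
    counts: np.ndarray
    mask: np.ndarray                  # occupied bins
    n_samples: int
    out_of_box: int
    metadata: dict = field(default_factory=dict)
    h: Optional[np.ndarray] = None

    @property
    def centers(self) -> list:
        return [0.5 * (e[1:] + e[:-1]) for e in self.edges]

    @property
    def dim(self) -> int:
        return len(self.edges)


def _make_edges(bounds, bins):
    return [np.linspace(lo, hi, m + 1) for (lo, hi), m in zip(bounds, bins)]


def _histogram_uniform(pts, bounds, bins, counts):
    """Accumulate counts for uniform bins; returns number of out-of-box points."""
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    nb = np.asarray(bins)
    width = (hi - lo) / nb
    idx = np.floor((pts - lo) / width).astype(np.int64)
    ok = np.all((idx >= 0) & (idx < nb), axis=-1)
    idx = idx[ok]
    flat = np.ravel_multi_index(idx.T, tuple(nb))
    counts += np.bincount(flat, minlength=int(np.prod(nb))).reshape(tuple(nb))
    return int(pts.shape[0] - idx.shape[0])


def _finalize_density(counts, edges, n_samples, out_of_box, metadata):
    mask = counts > 0
    total = counts[mask].sum()
    masses = np.zeros_like(counts, dtype=float)
    if total > 0:
        masses[mask] = counts[mask] / total
    return DensityGrid(
        edges=edges, masses=masses, counts=counts, mask=mask,
        n_samples=int(n_samples), out_of_box=int(out_of_box),
        metadata=metadata,
    )


def estimate_density(traj: EnsembleTrajectory, bounds, bins,
                     burn_in: int = 0) -> DensityGrid:
    """Histogram recorded post-burn-in states into a :class:`DensityGrid`.

    ``burn_in`` here discards additional leading *recorded* frames (on top
    of any burn-in already applied during simulation).  Out-of-box samples
    are counted, reported and excluded from normalization.
    """
    states = traj.states[:, burn_in:, :]
    if states.size == 0:
        raise ValueError("no post-burn-in samples")
    pts = states.reshape(-1, traj.dim).astype(float)
    edges = _make_edges(bounds, bins)
    counts = np.zeros(tuple(bins), dtype=np.int64)
    oob = _histogram_uniform(pts, bounds, bins, counts)
    if oob:
        frac = oob / pts.shape[0]
        if frac > 0.01:
            import warnings
            warnings.warn(f"{frac:.1%} of samples fall outside the grid box")
    return _finalize_density(
        counts, edges, pts.shape[0] - oob, oob,
        {"dt": traj.dt, "seed": traj.seed, "source": "estimate_density",
         **traj.system_meta},
    )


def simulate_density(
    system: SystemSpec,
    walkers: int,
    steps: int,
    dt: float,
    seed: int,
    init,
    bounds,
    bins,
    record_stride: int = 1,
    burn_in: Union[int, float, None] = None,
) -> DensityGrid:
    """Fused simulate + histogram: identical streams and binning as
    ``estimate_density(simulate_langevin(...))`` but without materialising
    the ensemble path (memory stays O(chunk), so ensemble sizes of 1e8+
    samples are routine)."""
    bi = _resolve_burn_in(burn_in, steps)
    edges = _make_edges(bounds, bins)
    counts = np.zeros(tuple(bins), dtype=np.int64)
    tally = {"oob": 0, "n": 0}

    def consume(w0, chunk):
        pts = chunk.reshape(-1, system.dim).astype(float)
        tally["oob"] += _histogram_uniform(pts, bounds, bins, counts)
        tally["n"] += pts.shape[0]

    _run_ensemble(system, walkers, steps, dt, seed, init, bi, record_stride,
                  consume)
    return _finalize_density(
        counts, edges, tally["n"] - tally["oob"], tally["oob"],
        {"dt": dt, "seed": seed, "walkers": walkers, "steps": steps,
         "burn_in": bi, "source": "simulate_density",
         "name": system.name, "params": system.params, "D": system.D},
    )


def cole_hopf(grid: DensityGrid, bandwidth: float = 1.5,
              edge_margin: int = 2) -> PotentialModel:
    """Empirical Cole-Hopf landscape h = -log(P_steady) from a density grid.

    Masses are smoothed with a Gaussian kernel (``bandwidth`` in bins,
    normalized convolution so empty bins never dilute occupied ones), the
    log is taken on the smoothed field, and h is offset to min 0 over the
    mask.  The gradient and Laplacian are tabulated by masked central
    differences and interpolated separately (interpolant-of-gradient,
    chosen for smoothness of the downstream typical-trajectory field);
    derivative queries within ``edge_margin`` bins of the mask edge are
    invalid.  Queries outside the mask evaluate to NaN rather than
    extrapolating.
    """
    if not np.any(grid.mask):
        raise ValueError("density grid has no occupied bins")
    mask = grid.mask
    if bandwidth and bandwidth > 0:
        m = mask.astype(float)
        sm = ndimage.gaussian_filter(grid.masses, sigma=bandwidth)
        norm = ndimage.gaussian_filter(m, sigma=bandwidth)
        # keep only bins with meaningful support from occupied neighbours
        support = norm > 0.5
        smoothed = np.where(support, sm / np.where(norm > 0, norm, 1.0), 0.0)
        mask = support & (smoothed > 0)
    else:
        smoothed = grid.masses

    h = np.full(grid.masses.shape, np.nan)
    h[mask] = -np.log(smoothed[mask])
    h[mask] -= np.nanmin(h[mask])
    grid.h = h

    centers = grid.centers
    steps = [float(c[1] - c[0]) for c in centers]
    dim = grid.dim

    grad_mask = ndimage.binary_erosion(mask, iterations=1)
    lap_mask = ndimage.binary_erosion(mask, iterations=max(edge_margin, 1))
    grads = []
    lap = np.full(h.shape, np.nan)
    lap_acc = np.zeros(h.shape)
    for ax in range(dim):
        g = np.full(h.shape, np.nan)
        fwd = np.roll(h, -1, axis=ax)
        bwd = np.roll(h, 1, axis=ax)
        g[grad_mask] = (fwd[grad_mask] - bwd[grad_mask]) / (2 * steps[ax])
        grads.append(g)
        lap_acc += np.where(lap_mask, (fwd - 2 * h + bwd) / steps[ax] ** 2, np.nan)
    lap[lap_mask] = lap_acc[lap_mask]

    def _interp(arr, fill=np.nan):
        rgi = RegularGridInterpolator(
            tuple(centers), arr, method="linear",
            bounds_error=False, fill_value=fill,
        )

        def f(p):
            p = np.asarray(p, dtype=float)
            return np.asarray(rgi(p.reshape(-1, dim))).reshape(p.shape[:-1])

        return f

    h_i = _interp(h)
    g_i = [_interp(g) for g in grads]
    lap_i = _interp(lap)
    mask_i = _interp(mask.astype(float), fill=0.0)

    lo = tuple(float(c[0]) for c in centers)
    hi = tuple(float(c[-1]) for c in centers)
    H = ScalarField(
        fn=h_i,
        dim=dim,
        grad=lambda p: np.stack([gi(p) for gi in g_i], axis=-1),
        lap=lap_i,
        provenance="grid_interpolated",
        domain=Box(lo, hi),
        fd_step=min(steps),
        name="h_empirical",
    )
    D = grid.metadata.get("D", np.nan)
    return PotentialModel(
        kind="empirical", H=H, D=float(D), source="cole_hopf",
        offset="min_zero",
        mask=lambda p: mask_i(p) > 0.999,
        metadata={"bandwidth": bandwidth, "bins": list(grid.masses.shape),
                  "n_samples": grid.n_samples},
    )
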