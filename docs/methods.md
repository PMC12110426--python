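# Methods

`nesskit` studies stationary measures of overdamped Langevin dynamics

    dx/dt = F(x) + xi,   <xi_i(t) xi_j(t')> = 2 D delta_ij delta(t - t'),

with additive noise of strength D (units [x]²/[t]).  The stationary
density P_stat of the associated Fokker–Planck equation

    0 = sum_i ∂_i ( -F_i P + D ∂_i P )

is represented throughout by its Cole–Hopf transform H = −log P_stat
(the "stochastic entropy" of the state).  This note records the model
assumptions, the sign and numerical conventions, and what the synthetic
experiments do and do not demonstrate.

## Orthogonal Helmholtz–Hodge decompositions

A drift F has a *perpendicular HHD* when it splits as

    F = −∇V + u,    ∇·u = 0,    u·∇V = 0.

Such systems break detailed balance (u drives persistent circulation)
yet their stationary measure is the equilibrium Boltzmann form
P ∝ exp(−V/D): substituting H = V/D into the stationary Fokker–Planck
operator, every u-dependent term is killed by the two orthogonality
conditions.  `hhd.check_orthogonal_hhd` quantifies deviation from this
structure by the max of |∇·u| and |u·∇V| over a declared sample,
normalized by max|u| and max|u|·max|∇V| respectively so that verdicts
are scale-free.  Verdict tolerances: 1e−8 (closed-form derivatives) and
1e−4 (the noise floor of central differences).  The package only
*verifies* declared decompositions; no general construction algorithm
for a perpendicular HHD is known, and none is attempted.

Built-in systems (module `models`; all planar, parameters as in the
worked examples they reproduce):

- `gradient_quadratic` — V = k|x|²/2, equilibrium reference.
- `hopf` — noisy Hopf oscillator, V = −(A/2)|x|² + (B/4)|x|⁴ with a rigid
  rotation u of rate Ω; a perpendicular HHD for any A, B, Ω.  Defaults
  A = B = 1.
- `suda_quadratic` — a quadratic planar flow with an exactly orthogonal
  polynomial decomposition; the declared parts carry the overall
  prefactor 1/26 (component-wise summation of the declared quadratics
  reproduces the total drift only with this prefactor, verified
  symbolically; the potential V = (19x³/3 − 9x²y + 7xy² − 17y³/3)/26 is
  reconstructed by integrating the declared gradient).
- `linear_example` — V = |x|²/2, rotation u, perturbation r = (y, 0)
  with strength λ: the exactly solvable (Gaussian) testbed for the
  perturbative machinery.
- `brusselator` — F = (μ + x²y − (b+1)x, bx − x²y), no declared parts
  (no polynomial perpendicular HHD exists).  The rate constant usually
  written λ in the chemical-oscillator literature is exposed as `b` to
  avoid clashing with the perturbation strength.  Defaults μ = 1, b = 3,
  D = 0.005.
- `linear_normal_system(A)` — F = Ax for normal A ([A, Aᵀ] = 0): V and u
  from the symmetric/antisymmetric split.
- `from_potential_antisym(V, A)` — u = A∇V with constant antisymmetric
  A; orthogonality and solenoidality are identities of this class.

## Perturbative stationary measures

Near-HHD systems F = −∇V + u + λr (λ ≪ 1) admit a first-order corrected
Cole–Hopf potential in the small-noise regime:

    P_stat ∝ exp( −(V + λ W_r) / D ),

where W_r solves the directional-derivative problem

    (∇V + u) · ∇W_r = − r · ∇V.

**Sign convention.**  The transcription chain that defines W_r is
internally ambiguous if taken term by term; the Fokker–Planck equation
is not.  We fix all signs by demanding that the residual of the
stationary FP operator applied to exp(−(V+λW_r)/D) be o(λ); for the
linear testbed this requirement is equivalent to the exact stationary
covariance of the linear SDE (Lyapunov equation), which gives

    W_r = −[2xy + Ω(x²−y²)] / (4(1+Ω²))      (u = (Ωy, −Ωx), r = (y,0)).

Both oracles are frozen into the test suite.  A consequence worth
stating explicitly: along the corrected typical trajectory (below) the
O(λ) change of P_stat cancels *exactly* at this order — the measured
rate is O(λ²), which the order-check test verifies by a Richardson
ratio (≈4 when λ is halved).  The closed form −(2λ/D)(r·∇V)P_stat
returned by `typical.near_hhd_rate` is therefore an *activity gauge* —
the magnitude of the cancelled contribution, and hence of the distance
to a perpendicular HHD — not the realised rate.

W_r is evaluated by characteristics: from each query point the
attracting descent flow −(∇V + u) is integrated (adaptive RK45 4/5
pair, rtol 1e−7 / atol 1e−9 by default) to a base point with ∇V ≈ 0,
accumulating the line integral of the source; W_r(base) = 0, so all
comparisons are offset-invariant.  Termination: |x − base| < 1e−6, or a
speed floor of 1e−8 flags a spurious fixed point; non-converged points
are flagged, never silently filled.  The O(D⁰) correction to g = W_r/D
is out of scope: the machinery targets the leading small-D form, and
the full (non-perturbative) Hopf correction is non-analytic in the
coordinates, which is precisely why no general closed form is pursued.

## Simulation and the empirical landscape

`simulate` provides a seeded Euler–Maruyama ensemble,

    x ← x + F(x) dt + sqrt(2 D dt) N(0, 1)   (per component),

the only scheme offered because the noise is additive and constant, so
the Itô/Stratonovich/Hänggi–Klimontovich readings coincide.  Each
walker owns a counter-based Philox stream keyed by (master seed, walker
index): results are bit-reproducible and unchanged when the walker
count or internal chunking changes.  Useful discrete-scheme facts used
as test oracles: the Euler–Maruyama Ornstein–Uhlenbeck recursion has
stationary variance 2Ddt/(1−(1−dt)²) = D/(1−dt/2), not D.

`estimate_density` histograms post-burn-in states on a regular grid
(half-open bins, masses normalized over occupied bins, out-of-box
samples counted and excluded); `simulate_density` fuses simulation and
histogramming through the same kernel so ensembles of 10⁸+ samples run
in O(chunk) memory bit-identically to the stored path.  Burn-in default:
the first 20% of steps.

`cole_hopf` builds the empirical landscape h = −log P_steady: optional
Gaussian smoothing of the masses (default bandwidth 1.5 bins, normalized
convolution so empty bins never dilute occupied ones, support threshold
0.5), offset so min h = 0, derivatives by masked central differences
tabulated once and interpolated bilinearly ("interpolant of gradient",
chosen over differentiating the interpolant for smoothness of the
downstream typical-trajectory field).  Derivatives within 2 bins of the
mask edge, and any query outside the mask, return NaN — flagged, never
extrapolated.

## Typical trajectories and their diagnostics

The typical trajectory is the deterministic flow

    dX/dt = F + D ∇H

(drift plus osmotic velocity); its Liouville dynamics leaves P_stat
invariant *as a density*, but pointwise along a path the stationary
probability changes at the rate

    dρ/dt = −ρ (D ΔH + ∇·F),

equivalently a stochastic entropy production dH/dt = −∇·(dX/dt).  For a
perpendicular HHD with H = V/D both vanish identically (D ΔH + ∇·F =
ΔV − ΔV + ∇·u): such systems "typically display detailed balance".  For
the Brusselator they do not — the drift is compressible (∇·F ≠ 0 and
not compensable), so P varies by orders of magnitude along one orbit.
`probability_rate` reports the divergence form and the chain-rule form
separately: they agree only when H is an exact stationary Cole–Hopf
transform, and their discrepancy is itself a stationarity diagnostic.
`entropy_production_rate` always reports the exact −(∇·F + DΔH); the
first-order reference −λ∇·r is attached for comparison but the ΔW_r
term it omits vanishes only for harmonic W_r (for r = (x,0) on the
quadratic well, ΔW_r = −1 cancels ∇·r = +1 exactly and the true rate is
zero — the exact Gaussian solution confirms this).

Orbit periods for spread statistics use a Poincaré section through the
start point normal to the initial typical velocity, first return in the
initial direction within a capture radius (default 0.5) — no hand-tuned
integration windows.

`omega_limit_descent` integrates the noise-free drift until |∇V| < tol:
for perpendicular-HHD flows the ω-limit set lies on ∇V = 0 regardless
of the persistent rotation (the Hopf descent lands on |x| = sqrt(A/B)).

## Weak-noise (Freidlin–Wentzell) expansion

For D → 0, P_stat ∝ exp(−(H0 + D H1 + …)/D).  The quasipotential H0
solves the stationary Hamilton–Jacobi equation F·∇H0 + (∇H0)² = 0 for
the Freidlin–Wentzell Hamiltonian H_FW = |p|² + F·p with momenta
p = (ẋ − F)/2; the relevant subspace is p = 0, where the mixed-Hessian
trace of H_FW equals ∇·F — phase-space compression — and modulates the
propagator amplitude exp(−∫ ∇·F dt) (`amplitude_along`).

The subleading correction H1 satisfies the stationary transport
equation, which we derive directly from the O(D⁰) term of the FP
operator applied to exp(−(H0/D + H1)):

    ∇·F − 2 ∇H0·∇H1 − F·∇H1 + ΔH0 = 0.

Two exact consequences pin this form down (both are tests): for a
perpendicular HHD (H0 = V) it reduces to (∇V + u)·∇H1 = 0, i.e. H1
constant, as the exact Boltzmann solution requires; and for linear
F = Ax with stationary covariance D·S (Lyapunov equation
AS + SAᵀ = −2·Id), H0 = xᵀS⁻¹x/2 with H1 = 0 satisfies it through the
trace identity Tr A + Tr S⁻¹ = 0.  `solve_H1_characteristics` solves
the transport equation along characteristics of the ascent flow
2∇H0 + F, reusing the W_r descent integrator with source ∇·F + ΔH0.

First-order trajectory corrections X = X0 + D X1: Ẋ0 = F + ∇H0 (for a
perpendicular HHD this is just the solenoidal flow u) and
Ẋ1 = ∇H1 + q∇H0 with q = −(∇·F + ΔH0)/|∇H0|², the minimal
representative of a family defined up to fields orthogonal to ∇H0.  A
guard |∇H0|² ≥ 1e−10 rejects queries near the critical set, where the
correction is undefined.  No Hamilton–Jacobi boundary-value solver is
included: H0 enters as a closed form (HHD case, linear case) or as the
empirical D·h surrogate, with the caveat that an empirical landscape
carries Monte-Carlo noise into second derivatives.

## The scaled-down Brusselator experiment

`pipelines.brusselator_probability_spread` reproduces the qualitative
nonequilibrium phenomenology of the noisy Brusselator (μ = 1, b = 3,
D = 0.005): 5×10³ walkers × 4×10⁴ Euler–Maruyama steps at dt = 1e−3,
20% burn-in (≈1.6×10⁸ recorded samples), histogrammed on a 250×300 grid
over [0,5]×[0,6], smoothed at 1.5 bins; the typical trajectory is
integrated from a point on the deterministic limit cycle for one
Poincaré period and the spread log10(max P/min P) along it is reported.
These ensemble sizes are the package's chosen operating point: they are
large enough that the landscape in the visited tube is converged (the
spread statistic is reproducible across seeds within ±0.5 decades,
asserted over three seeds) while keeping a single run around a minute.
Typical output: spread ≈ 1.8–2.1 decades, period ≈ 7.1.

What the synthetic experiments do *not* show: behaviour of the
landscape tails (empty-bin mask excludes them), many-body active
systems (flocking, MIPS — only planar model flows are implemented), the
non-perturbative Hopf correction, and the D → 0 limit for systems with
non-hyperbolic attractors, where a stationary measure independent of
initial conditions exists only at finite noise.

## Numerical choices at a glance

| Choice | Default | Rationale |
|---|---|---|
| FD step (closed-form check fallback) | 1e−5 absolute | O(step²) truncation vs roundoff balance |
| Decomposition verdict tolerance | 1e−8 / 1e−4 (closed/FD) | scheme noise floors |
| ODE integrator | RK45, rtol 1e−7, atol 1e−9 | adaptive 4/5 pair |
| W_r base radius / speed floor | 1e−6 / 1e−8 | termination vs spurious fixed points |
| Histogram bins (Brusselator) | 250×300 | ~2×10³ samples per occupied bin |
| Smoothing bandwidth | 1.5 bins | stabilises ∇h without biasing the valley |
| Burn-in | 20% of steps | beyond the slowest relaxation observed |
| Critical-set guard | \|∇H0\|² ≥ 1e−10 | q undefined at ∇H0 = 0 |

Degenerate inputs: D = 0 is accepted by the simulator (deterministic
integration) but refused by every Cole–Hopf construction; stalled
typical trajectories (|Ẋ| below floor) terminate with a flag; blow-ups
name the walker, step and state.
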