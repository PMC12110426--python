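import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.linalg import solve_continuous_lyapunov

from nesskit import (
    amplitude_along,
    assemble_system,
    boltzmann_potential,
    compression_trace,
    first_order_velocity,
    fw_hamiltonian,
    hj_residual,
    linear_normal_system,
    make_model,
    solve_H1_characteristics,
    transport_residual,
    typical_trajectory,
)
from nesskit.fields import ScalarField, VectorField

from conftest import linear_example, quadratic_V


def const_field(value=0.0, dim=2):
    return ScalarField(
        fn=lambda p: np.full(np.asarray(p).shape[:-1], value), dim=dim,
        grad=lambda p: np.zeros(np.asarray(p, float).shape),
        lap=lambda p: np.zeros(np.asarray(p).shape[:-1]))


def rotation_system(D=0.1):
    u = VectorField(
        fn=lambda p: np.stack([p[..., 1], -p[..., 0]], axis=-1), dim=2,
        div=lambda p: np.zeros(np.asarray(p).shape[:-1]))
    return assemble_system(F=u, D=D, dim=2)


class TestFWHamiltonian:
    def test_vanishes_on_zero_momentum_subspace(self, brusselator, rng):
        pts = rng.uniform(0.2, 3.0, size=(20, 2))
        assert np.allclose(
            fw_hamiltonian(brusselator, pts, np.zeros_like(pts)), 0.0)

    def test_linear_drift_arithmetic(self):
        sys_ = make_model("gradient_quadratic", k=1.0, D=0.1)  # F = -x
        assert fw_hamiltonian(sys_, np.array([1.0, 0.0]),
                              np.array([1.0, 0.0])) == pytest.approx(0.0)

    def test_momentum_gradV_on_hhd_instanton_manifold(self, hopf, rng):
        # p = gradH0 with H0 = V: |gradV|^2 + F.gradV = u.gradV = 0
        pts = rng.uniform(-1.5, 1.5, size=(30, 2))
        vals = fw_hamiltonian(hopf, pts, hopf.V.gradient(pts))
        assert np.max(np.abs(vals)) < 1e-12


class TestCompressionTrace:
    def test_brusselator_at_fixed_point(self, brusselator):
        closed, numeric = compression_trace(brusselator, np.array([1.0, 3.0]))
        assert closed == pytest.approx(1.0, abs=1e-12)
        assert numeric == pytest.approx(1.0, abs=1e-4)

    def test_hopf_at_origin(self, hopf):
        # divF = -LapV = 2A at the origin
        closed, numeric = compression_trace(hopf, np.zeros(2))
        assert closed == pytest.approx(2.0, abs=1e-12)
        assert numeric == pytest.approx(2.0, abs=1e-4)

    def test_divergence_free_flow(self, rng):
        sys_ = rotation_system()
        for pt in rng.uniform(-2, 2, size=(5, 2)):
            closed, numeric = compression_trace(sys_, pt)
            assert abs(closed) < 1e-12
            assert abs(numeric) < 1e-6

    @settings(max_examples=30, deadline=None)
    @given(coef=st.lists(st.floats(-2, 2, allow_nan=False), min_size=6,
                         max_size=6),
           x=st.floats(-1.5, 1.5), y=st.floats(-1.5, 1.5))
    def test_property_identity_for_random_quadratic_fields(self, coef, x, y):
        # mixed-Hessian trace of H_FW at p=0 equals divF for polynomial F
        a, b, c, d, e, f = coef

        def F_fn(p):
            X, Y = p[..., 0], p[..., 1]
            return np.stack([a * X**2 + b * X * Y + c * Y**2,
                             d * X**2 + e * X * Y + f * Y**2], axis=-1)

        sys_ = assemble_system(
            F=VectorField(fn=F_fn, dim=2,
                          div=lambda p: 2 * a * p[..., 0] + b * p[..., 1]
                          + e * p[..., 0] + 2 * f * p[..., 1]),
            D=0.1, dim=2)
        closed, numeric = compression_trace(sys_, np.array([x, y]))
        assert abs(closed - numeric) < 1e-4 * max(1.0, abs(closed))


class TestHJResidual:
    @pytest.mark.parametrize("name,kw", [
        ("hopf", dict(A=1.0, B=1.0, Omega=2.0, D=0.1)),
        ("suda_quadratic", dict(D=0.1)),
        ("gradient_quadratic", dict(k=1.0, D=0.5)),
        ("linear_example", dict(Omega=1.0, lam=0.0, D=0.1)),
    ])
    def test_quasipotential_V_solves_hj_for_hhd_zoo(self, name, kw, rng):
        sys_ = make_model(name, **kw)
        pts = rng.uniform(-1.5, 1.5, size=(60, 2))
        assert np.max(np.abs(hj_residual(sys_, sys_.V, pts))) < 1e-10

    def test_constant_H0_degenerate_solution(self, brusselator, rng):
        pts = rng.uniform(0.5, 2.0, size=(20, 2))
        assert np.allclose(hj_residual(brusselator, const_field(3.0), pts), 0.0)

    def test_nonnormal_linear_quasipotential_from_lyapunov(self, rng):
        # no perpendicular HHD, but the exact Gaussian H0 = x^T S^-1 x / 2
        # with A S + S A^T = -2 I still solves the stationary HJ equation
        A = np.array([[-1.0, 2.0], [0.0, -1.0]])
        S = solve_continuous_lyapunov(A, -2.0 * np.eye(2))
        assert np.allclose(S, [[3.0, 1.0], [1.0, 1.0]])  # frozen oracle
        Sinv = np.linalg.inv(S)
        H0 = ScalarField(
            fn=lambda p: 0.5 * np.einsum("...i,ij,...j->...",
                                         np.asarray(p, float), Sinv,
                                         np.asarray(p, float)),
            dim=2, grad=lambda p: np.asarray(p, float) @ Sinv.T,
            lap=lambda p: np.full(np.asarray(p).shape[:-1],
                                  float(np.trace(Sinv))))
        F = VectorField(fn=lambda p: np.asarray(p, float) @ A.T, dim=2,
                        div=lambda p: np.full(np.asarray(p).shape[:-1],
                                              float(np.trace(A))))
        sys_ = assemble_system(F=F, D=0.1, dim=2)
        pts = rng.uniform(-2, 2, size=(50, 2))
        assert np.max(np.abs(hj_residual(sys_, H0, pts))) < 1e-10

    def test_brusselator_quadratic_guess_fails(self, brusselator):
        guess = ScalarField(
            fn=lambda p: 0.5 * ((p[..., 0] - 1) ** 2 + (p[..., 1] - 3) ** 2),
            dim=2,
            grad=lambda p: np.stack([p[..., 0] - 1, p[..., 1] - 3], axis=-1))
        pts = np.array([[2.0, 1.0], [0.5, 2.5], [3.0, 4.0]])
        assert np.min(np.abs(hj_residual(brusselator, guess, pts))) > 0.1


class TestTransport:
    def test_constant_H1_closes_hhd_transport(self, hopf, rng):
        pts = rng.uniform(-1.5, 1.5, size=(40, 2))
        res = transport_residual(hopf, hopf.V, const_field(), pts)
        assert np.max(np.abs(res)) < 1e-12

    def test_divergence_free_flow_harmonic_H0(self, rng):
        # divF = 0 and Lap H0 = 0 with H1 = 0: residual vanishes
        sys_ = rotation_system()
        H0 = ScalarField(fn=lambda p: p[..., 0] * p[..., 1], dim=2,
                         grad=lambda p: np.stack([p[..., 1], p[..., 0]],
                                                 axis=-1),
                         lap=lambda p: np.zeros(np.asarray(p).shape[:-1]))
        pts = rng.uniform(-1, 1, size=(20, 2))
        assert np.allclose(transport_residual(sys_, H0, const_field(), pts),
                           0.0, atol=1e-12)

    def test_lyapunov_trace_identity_nonnormal_linear(self, rng):
        # Tr A + Tr S^-1 = 0 makes H1 = 0 exact for linear flow
        A = np.array([[-1.0, 2.0], [0.0, -1.0]])
        S = solve_continuous_lyapunov(A, -2.0 * np.eye(2))
        Sinv = np.linalg.inv(S)
        assert abs(np.trace(A) + np.trace(Sinv)) < 1e-12
        H0 = ScalarField(
            fn=lambda p: 0.5 * np.einsum("...i,ij,...j->...",
                                         np.asarray(p, float), Sinv,
                                         np.asarray(p, float)),
            dim=2, grad=lambda p: np.asarray(p, float) @ Sinv.T,
            lap=lambda p: np.full(np.asarray(p).shape[:-1],
                                  float(np.trace(Sinv))))
        F = VectorField(fn=lambda p: np.asarray(p, float) @ A.T, dim=2,
                        div=lambda p: np.full(np.asarray(p).shape[:-1],
                                              float(np.trace(A))))
        sys_ = assemble_system(F=F, D=0.1, dim=2)
        pts = rng.uniform(-2, 2, size=(30, 2))
        assert np.max(np.abs(
            transport_residual(sys_, H0, const_field(), pts))) < 1e-12

    def test_characteristics_give_constant_H1_for_hhd(self, rng):
        # for perpendicular-HHD systems the transport source vanishes, so
        # H1 is constant (zero with the base normalisation)
        for sys_ in (make_model("gradient_quadratic", k=1.0, D=0.5),
                     linear_example(Omega=1.0, lam=0.0, D=0.1)):
            pts = rng.uniform(-1.5, 1.5, size=(8, 2))
            res = solve_H1_characteristics(sys_, sys_.V, (0.0, 0.0), pts)
            assert res.converged.all()
            assert np.max(np.abs(res.values)) < 1e-7


class TestAmplitude:
    def test_divergence_free_amplitude_is_one(self, rng):
        sys_ = rotation_system()
        t = np.linspace(0, 5, 100)
        path = np.stack([np.cos(t), np.sin(t)], axis=-1)
        assert np.allclose(amplitude_along(sys_, t, path), 1.0)

    def test_linear_contraction_amplitude(self):
        # F = -x: divF = -2 so A(t) = e^{2t}
        sys_ = make_model("gradient_quadratic", k=1.0, D=0.1)
        t = np.linspace(0, 3, 50)
        path = np.stack([np.exp(-t), np.zeros_like(t)], axis=-1)
        amp = amplitude_along(sys_, t, path)
        assert np.allclose(amp, np.exp(2 * t), rtol=1e-10)

    def test_non_monotone_times_rejected(self):
        sys_ = rotation_system()
        with pytest.raises(ValueError, match="increasing"):
            amplitude_along(sys_, np.array([0.0, 1.0, 0.5]), np.zeros((3, 2)))


class TestFirstOrderVelocity:
    def test_hhd_zeroth_order_is_solenoidal_flow(self, hopf, rng):
        for pt in rng.uniform(0.3, 1.5, size=(10, 2)):
            X0dot, _ = first_order_velocity(hopf, hopf.V, None, pt)
            assert np.allclose(X0dot, hopf.u(pt), atol=1e-12)

    def test_gradient_quadratic_q_vanishes(self, gradient_quadratic):
        # divF = -LapV so q = 0 and Xdot1 = gradH1
        H1 = ScalarField(fn=lambda p: p[..., 0], dim=2,
                         grad=lambda p: np.stack(
                             [np.ones(np.asarray(p).shape[:-1]),
                              np.zeros(np.asarray(p).shape[:-1])], axis=-1))
        X0dot, X1dot = first_order_velocity(
            gradient_quadratic, gradient_quadratic.V, H1, np.array([1.0, 1.0]))
        assert np.allclose(X0dot, 0.0, atol=1e-12)
        assert np.allclose(X1dot, [1.0, 0.0], atol=1e-12)

    def test_critical_set_guarded(self, hopf):
        with pytest.raises(ValueError, match="critical"):
            first_order_velocity(hopf, hopf.V, None, np.zeros(2))

    def test_typical_trajectory_approaches_X0_path_linearly_in_D(self):
        """With H = H0/D + H1 the typical velocity is Xdot0 + D gradH1:
        over a fixed window the sup-distance to the D=0 path shrinks
        linearly in D."""
        base = linear_example(Omega=1.0, lam=0.0, D=1.0)
        V = base.V

        def H1_fn(p):
            return 0.3 * np.sin(p[..., 0]) + 0.2 * p[..., 1]

        def H1_grad(p):
            return np.stack([0.3 * np.cos(p[..., 0]),
                             np.full(np.asarray(p).shape[:-1], 0.2)], axis=-1)

        from nesskit.stationary import PotentialModel
        from nesskit.typical import typical_trajectory as integrate

        x0, window = (1.0, 0.0), (0.0, 3.0)
        sups = []
        Ds = (0.2, 0.1, 0.05)
        # reference: D -> 0 path, Xdot0 = F + gradH0 = u
        sys0 = linear_example(Omega=1.0, lam=0.0, D=1e-12)
        ref_t = np.linspace(*window, 400)
        ref = np.stack([np.cos(ref_t), -np.sin(ref_t)], axis=-1)  # u-rotation
        for D in Ds:
            sys_ = linear_example(Omega=1.0, lam=0.0, D=D)
            H = ScalarField(
                fn=lambda p, D=D: V.fn(p) / D + H1_fn(p),
                dim=2,
                grad=lambda p, D=D: V.grad(p) / D + H1_grad(p))
            pot = PotentialModel(kind="analytic", H=H, D=D)
            traj = integrate(sys_, pot, x0, window, n_eval=400)
            sups.append(np.max(np.linalg.norm(traj.X - ref, axis=1)))
        assert 1.8 < sups[0] / sups[1] < 2.2
        assert 1.8 < sups[1] / sups[2] < 2.2
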