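import numpy as np
import pytest

from nesskit import ScalarField, VectorField, assemble_system, make_model


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def hopf():
    return make_model("hopf", A=1.0, B=1.0, Omega=2.0, D=0.1)


@pytest.fixture
def suda():
    return make_model("suda_quadratic", D=0.1)


@pytest.fixture
def brusselator():
    return make_model("brusselator", mu=1.0, b=3.0, D=0.005)


@pytest.fixture
def gradient_quadratic():
    return make_model("gradient_quadratic", k=1.0, D=0.5)


def linear_example(Omega=1.0, lam=0.05, D=0.02):
    return make_model("linear_example", Omega=Omega, lam=lam, D=D)


@pytest.fixture(name="linear_example")
def linear_example_fixture():
    return linear_example()


def quadratic_V(dim=2, k=1.0):
    return ScalarField(
        fn=lambda p: 0.5 * k * np.sum(np.asarray(p, float) ** 2, axis=-1),
        dim=dim,
        grad=lambda p: k * np.asarray(p, float),
        lap=lambda p: np.full(np.asarray(p).shape[:-1], k * dim),
    )


def zero_vector_field(dim=2):
    return VectorField(
        fn=lambda p: np.zeros(np.asarray(p, float).shape),
        dim=dim,
        div=lambda p: np.zeros(np.asarray(p).shape[:-1]),
    )


def exact_linear_wr_coeffs(Omega):
    """Exact first-order correction for the linear near-HHD testbed,
    derived from the stationary covariance of the linear SDE:
    W_r = a xy + b (x^2 - y^2)."""
    a = -1.0 / (2.0 * (1.0 + Omega**2))
    b = -Omega / (4.0 * (1.0 + Omega**2))
    return a, b
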