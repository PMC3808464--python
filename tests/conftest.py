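import numpy as np
import pytest

from sdngc import ARBEKKModel, JointARBEKKModel, simulate


def scalar_model(a=0.5, b=0.5, w=1.0) -> ARBEKKModel:
    B = [np.array([[b]])] if b != 0 else []
    return ARBEKKModel(A=[np.array([[a]])], B=B, W_chol=np.array([[np.sqrt(w)]]))


def scalar_pair_model(a=0.5, b=0.4, a_xy=0.0, b_xy=0.0, a_yx=0.0, b_yx=0.0,
                      w=1.0) -> JointARBEKKModel:
    sw = np.sqrt(w)
    return JointARBEKKModel(
        kx=1, ky=1,
        A=[np.array([[a, a_xy], [a_yx, a]])],
        Bx=[np.array([[b, b_xy]])],
        By=[np.array([[b_yx, b]])],
        Wx_chol=np.array([[sw]]),
        Wy_chol=np.array([[sw]]),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def base_model():
    """The reference scalar AR-BEKK model a=0.5, b=0.5, w=1."""
    return scalar_model()


@pytest.fixture
def base_panel(base_model):
    return simulate(base_model, T=1000, n_trials=2, seed=7)


def random_stable_scalar_models(rng, n, q_zero_fraction=0.0):
    """Random stable scalar models for property tests."""
    models = []
    while len(models) < n:
        a = rng.uniform(-0.9, 0.9)
        b = 0.0 if rng.random() < q_zero_fraction else rng.uniform(0.0, 0.9)
        if a * a + b * b < 0.98:
            w = rng.uniform(0.2, 2.0)
            models.append(scalar_model(a, b, w))
    return models
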