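import numpy as np
import pytest

from canred import (
    GLVModel,
    SSystem,
    gma_to_glv,
    make_toy_model,
    ssystem_to_gma,
)


@pytest.fixture
def toy() -> SSystem:
    return make_toy_model()


@pytest.fixture
def toy_glv(toy) -> GLVModel:
    return gma_to_glv(ssystem_to_gma(toy))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20160921)


def random_ssystem(rng: np.random.Generator, n: int, max_tries: int = 50) -> SSystem:
    """Random s-system with an invertible G - H (generic steady state)."""
    for _ in range(max_tries):
        alpha = rng.uniform(0.5, 2.0, n)
        beta = rng.uniform(0.5, 2.0, n)
        G = rng.uniform(-1.0, 1.0, (n, n))
        H = rng.uniform(-1.0, 1.0, (n, n))
        s = np.linalg.svd(G - H, compute_uv=False)
        if s[-1] <= 1e-6 * s[0]:
            continue
        # keep the steady state in a physiological range (|log x*| modest)
        logx = np.linalg.solve(G - H, np.log(beta / alpha))
        if np.max(np.abs(logx)) < 3.0:
            return SSystem(alpha, beta, G, H)
    raise RuntimeError("could not draw an invertible random s-system")


def random_glv(rng: np.random.Generator, n: int, m: int,
               steady_state=None) -> GLVModel:
    """Random GLV; if ``steady_state`` is given, lam is chosen so it holds."""
    A = rng.uniform(-1.0, 1.0, (n, m))
    B = rng.uniform(-1.0, 1.0, (m, n))
    if steady_state is None:
        lam = rng.uniform(-1.0, 1.0, n)
    else:
        q = np.exp(B @ np.log(np.asarray(steady_state, float)))
        lam = -A @ q
    return GLVModel(lam, A, B)
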