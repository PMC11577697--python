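import numpy as np
import pytest

import odsreg as o


def random_params(family: o.ModelFamily, rng: np.random.Generator) -> o.Parameters:
    """Moderate random parameters valid for the family."""
    m = family.K - 1
    if family.name == "cm":
        alpha = np.sort(rng.normal(scale=1.0, size=m))
        alpha += np.arange(m) * 1e-3  # guard against ties
    else:
        alpha = rng.normal(scale=1.0, size=m)
    beta = rng.normal(scale=0.7, size=family.p)
    phi = None
    if family.name == "sm":
        phi = np.empty(family.K)
        phi[0], phi[-1] = 1.0, 0.0
        phi[1:-1] = rng.uniform(0.0, 1.0, family.K - 2)
    return o.Parameters(alpha, beta, phi)


def draw_outcomes(
    probs: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    cum = np.cumsum(probs, axis=1)[:, :-1]
    u = rng.random(probs.shape[0])
    return 1 + (u[:, None] > cum).sum(axis=1)


def make_sample(
    family: o.ModelFamily,
    params: o.Parameters,
    n: int,
    rng: np.random.Generator,
    weights: bool = False,
) -> o.SampleData:
    X = rng.normal(size=(n, family.p))
    probs = o.category_probs(family, params, X)
    y = draw_outcomes(probs, rng)
    w = rng.uniform(0.5, 4.0, n) if weights else None
    return o.SampleData(y, X, w)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def irls_logistic(
    y01: np.ndarray, Xd: np.ndarray, w: np.ndarray, tol: float = 1e-12
) -> np.ndarray:
    """Independent weighted logistic IRLS oracle.

    ``Xd`` includes the intercept column; returns the coefficient vector for
    ``logit Pr(y01 = 1) = Xd @ coef``.
    """
    coef = np.zeros(Xd.shape[1])
    for _ in range(100):
        eta = Xd @ coef
        mu = 1.0 / (1.0 + np.exp(-eta))
        W = w * mu * (1.0 - mu)
        grad = Xd.T @ (w * (y01 - mu))
        H = Xd.T @ (Xd * W[:, None])
        step = np.linalg.solve(H, grad)
        coef = coef + step
        if np.max(np.abs(step)) < tol:
            break
    return coef
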