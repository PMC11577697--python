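"""Ordinal regression model families.

Four families are supported, all with a shared slope vector ``beta``
(proportional-odds style) and category intercepts ``alpha``:

``sm``
    Stereotype model: baseline-category logits ``alpha_k + phi_k * beta'x``
    with score parameters ``phi`` fixed at ``phi_1 = 1`` and ``phi_K = 0``
    for identifiability.
``ac``
    Adjacent-category logit: ``log(pi_k / pi_{k+1}) = alpha_k + beta'x``.
``cr``
    Continuation-ratio logit: ``log(pi_k / (pi_{k+1}+...+pi_K)) =
    alpha_k + beta'x``.
``cm``
    Cumulative logit (proportional odds): ``logit Pr(Y <= k) =
    alpha_k + beta'x``.

Outcomes are coded ``1..K`` ascending.  All functions are pure and
vectorised over the rows of the covariate matrix.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logsumexp

FAMILY_NAMES = ("sm", "ac", "cr", "cm")


class InvalidParameterError(ValueError):
    """Raised when parameters produce an invalid probability model."""


@dataclass(frozen=True)
class ModelFamily:
    """A model family tag: which logit, how many categories and covariates."""

    name: str
    K: int
    p: int

    def __post_init__(self) -> None:
        if self.name not in FAMILY_NAMES:
            raise ValueError(f"unknown family {self.name!r}; choose from {FAMILY_NAMES}")
        if self.K < 2:
            raise ValueError("K must be >= 2")
        if self.p < 0:
            raise ValueError("p must be >= 0")

    @property
    def n_params(self) -> int:
        """Number of free parameters: 2K-3+p for sm, K-1+p otherwise."""
        if self.name == "sm":
            return 2 * self.K - 3 + self.p
        return self.K - 1 + self.p

    @property
    def n_free_phi(self) -> int:
        return self.K - 2 if self.name == "sm" else 0


@dataclass
class Parameters:
    """Parameter values for one family.

    ``alpha`` has length K-1.  For the stereotype model ``phi`` is the full
    length-K score vector including the fixed endpoints ``phi[0] == 1`` and
    ``phi[-1] == 0``; for the other families it is ``None``.
    """

    alpha: np.ndarray
    beta: np.ndarray
    phi: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.alpha = np.atleast_1d(np.asarray(self.alpha, dtype=float))
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        if self.phi is not None:
            self.phi = np.atleast_1d(np.asarray(self.phi, dtype=float))
            if abs(self.phi[0] - 1.0) > 1e-12 or abs(self.phi[-1]) > 1e-12:
                raise InvalidParameterError(
                    "stereotype scores must satisfy phi[0] == 1 and phi[-1] == 0"
                )

    def copy(self) -> "Parameters":
        return Parameters(
            self.alpha.copy(),
            self.beta.copy(),
            None if self.phi is None else self.phi.copy(),
        )


def param_names(family: ModelFamily) -> list[str]:
    """Names of the free parameters in packing order."""
    names = [f"alpha{k}" for k in range(1, family.K)]
    if family.name == "sm":
        names += [f"phi{k}" for k in range(2, family.K)]
    names += [f"beta{j}" for j in range(1, family.p + 1)]
    return names


def pack(family: ModelFamily, params: Parameters) -> np.ndarray:
    """Flatten a Parameters object into the free-parameter vector."""
    _check_dims(family, params)
    parts = [params.alpha]
    if family.name == "sm":
        parts.append(params.phi[1 : family.K - 1])
    parts.append(params.beta)
    return np.concatenate(parts)


def unpack(family: ModelFamily, theta: np.ndarray) -> Parameters:
    """Inverse of :func:`pack`."""
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (family.n_params,):
        raise ValueError(
            f"theta has shape {theta.shape}, expected ({family.n_params},)"
        )
    m = family.K - 1
    alpha = theta[:m]
    if family.name == "sm":
        phi = np.empty(family.K)
        phi[0] = 1.0
        phi[-1] = 0.0
        phi[1 : family.K - 1] = theta[m : m + family.K - 2]
        beta = theta[m + family.K - 2 :]
        return Parameters(alpha, beta, phi)
    return Parameters(alpha, theta[m:])


def _check_dims(family: ModelFamily, params: Parameters) -> None:
    if params.alpha.shape != (family.K - 1,):
        raise ValueError(
            f"alpha has shape {params.alpha.shape}, expected ({family.K - 1},)"
        )
    if params.beta.shape != (family.p,):
        raise ValueError(
            f"beta has shape {params.beta.shape}, expected ({family.p},)"
        )
    if family.name == "sm":
        if params.phi is None or params.phi.shape != (family.K,):
            raise InvalidParameterError(
                f"stereotype model requires a length-{family.K} phi vector"
            )
    elif params.phi is not None:
        # phi silently ignored for ac/cr/cm per the family definitions
        pass


def _linear_score(family: ModelFamily, params: Parameters, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X.reshape(-1, family.p) if family.p else X.reshape(len(X), 0)
    if X.shape[1] != family.p:
        raise ValueError(f"X has {X.shape[1]} columns, expected {family.p}")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite values")
    return X @ params.beta


def log_category_probs(
    family: ModelFamily, params: Parameters, X: np.ndarray
) -> np.ndarray:
    """n x K matrix of log category probabilities."""
    _check_dims(family, params)
    s = _linear_score(family, params, X)
    n, K, m = len(s), family.K, family.K - 1

    if family.name in ("sm", "ac"):
        if family.name == "sm":
            eta = params.alpha[None, :] + np.outer(s, params.phi[:m])
        else:
            # adjacent-category as baseline-category logits: reverse cumsum
            # intercepts, scores K-k (equivalent stereotype re-expression)
            acc = np.cumsum(params.alpha[::-1])[::-1]
            scores = np.arange(m, 0, -1, dtype=float)
            eta = acc[None, :] + np.outer(s, scores)
        eta_full = np.concatenate([eta, np.zeros((n, 1))], axis=1)
        return eta_full - logsumexp(eta_full, axis=1, keepdims=True)

    if family.name == "cr":
        eta = params.alpha[None, :] + s[:, None]
        # log(1 + exp(eta)), overflow safe
        lse = np.logaddexp(0.0, eta)
        cum = np.cumsum(lse, axis=1)
        logp = np.empty((n, K))
        logp[:, :m] = eta - cum
        logp[:, m] = -cum[:, -1]
        return logp

    # cm
    if m > 1 and not np.all(np.diff(params.alpha) > 0):
        raise InvalidParameterError(
            "cumulative-logit intercepts must be strictly increasing"
        )
    gamma = np.empty((n, K + 1))
    gamma[:, 0] = 0.0
    gamma[:, K] = 1.0
    gamma[:, 1:K] = expit(params.alpha[None, :] + s[:, None])
    pi = np.diff(gamma, axis=1)
    if np.any(pi < 0):
        raise InvalidParameterError("cumulative-logit probabilities are negative")
    with np.errstate(divide="ignore"):
        return np.log(pi)


def category_probs(
    family: ModelFamily, params: Parameters, X: np.ndarray
) -> np.ndarray:
    """n x K row-stochastic matrix of category probabilities."""
    return np.exp(log_category_probs(family, params, X))


def loglik_contributions(
    family: ModelFamily,
    params: Parameters,
    y: np.ndarray,
    X: np.ndarray,
) -> np.ndarray:
    """Per-unit log-likelihood ``l_i = log pi_{i, y_i}``."""
    y = np.asarray(y)
    if np.any((y < 1) | (y > family.K)) or not np.issubdtype(y.dtype, np.integer):
        raise ValueError(f"outcomes must be integers in 1..{family.K}")
    logp = log_category_probs(family, params, X)
    return logp[np.arange(len(y)), y - 1]


def reverse_categories(family: ModelFamily, params: Parameters) -> Parameters:
    """Parameters of the same family after reversing the category order.

    Relabelling ``k -> K+1-k`` stays inside the family for sm, ac and cm
    (with the mapped parameters returned here); the continuation-ratio
    family is not closed under reversal and raises.

    For sm: ``alpha'_k = alpha_{K+1-k} - alpha_1`` (with ``alpha_K = 0``),
    ``phi'_k = 1 - phi_{K+1-k}`` and ``beta' = -beta``.  For ac and cm:
    ``alpha'_k = -alpha_{K-k}``, ``beta' = -beta``.
    """
    K = family.K
    if family.name == "sm":
        alpha_full = np.concatenate([params.alpha, [0.0]])  # alpha_K = 0
        new_alpha = alpha_full[::-1][:-1] - params.alpha[0]
        new_phi = 1.0 - params.phi[::-1]
        return Parameters(new_alpha, -params.beta, new_phi)
    if family.name in ("ac", "cm"):
        return Parameters(-params.alpha[::-1], -params.beta)
    raise ValueError(
        f"family {family.name!r} is not closed under category reversal"
    )


def ac_as_sm(params_ac: Parameters, K: int) -> Parameters:
    """Re-express adjacent-category parameters as an equivalent stereotype model.

    The adjacent-category logit equals a stereotype model with intercepts
    ``sum_{h>=k} alpha_h`` and fixed, equally spaced scores ``K-k``.  The
    returned object uses the package convention ``phi_1 = 1`` (scores
    ``(K-k)/(K-1)``), which rescales the slopes to ``(K-1) * beta``.
    """
    if params_ac.alpha.shape != (K - 1,):
        raise ValueError("alpha must have length K-1")
    alpha_sm = np.cumsum(params_ac.alpha[::-1])[::-1]
    phi = np.arange(K - 1, -1, -1, dtype=float) / (K - 1)
    beta_sm = (K - 1) * params_ac.beta
    return Parameters(alpha_sm, beta_sm, phi)
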