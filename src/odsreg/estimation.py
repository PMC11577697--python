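"""Maximum (pseudo-)likelihood estimation for the four ordinal families.

The weighted log pseudo-likelihood ``l_w(theta) = sum_i w_i l_i(theta)`` is
maximised by damped Newton iterations using analytic per-unit scores and the
analytic observed information.  With unit weights this is ordinary maximum
likelihood.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .families import (
    InvalidParameterError,
    ModelFamily,
    Parameters,
    ac_as_sm,
    loglik_contributions,
    pack,
    param_names,
    unpack,
)

__all__ = [
    "SampleData",
    "FitResult",
    "fit",
    "score_and_info",
    "per_unit_scores",
    "NonConvergenceWarning",
]


class NonConvergenceWarning(UserWarning):
    pass


@dataclass
class SampleData:
    """Outcome vector (coded 1..K), covariate matrix and optional weights."""

    y: np.ndarray
    X: np.ndarray
    w: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y)
        if not np.issubdtype(self.y.dtype, np.integer):
            yf = np.asarray(self.y, dtype=float)
            if not np.all(yf == np.round(yf)):
                raise ValueError("outcome values must be integers")
            self.y = yf.astype(int)
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim == 1:
            self.X = self.X[:, None]
        if self.X.shape[0] != len(self.y):
            raise ValueError("X and y have different numbers of rows")
        if self.w is None:
            self.w = np.ones(len(self.y))
        else:
            self.w = np.asarray(self.w, dtype=float)
            if self.w.shape != self.y.shape:
                raise ValueError("w and y have different lengths")
            if not np.all(np.isfinite(self.w)) or np.any(self.w <= 0):
                raise ValueError("weights must be strictly positive and finite")

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def observed_K(self) -> int:
        return int(self.y.max())


@dataclass
class FitResult:
    family: ModelFamily
    params: Parameters
    theta: np.ndarray
    loglik: float
    score: np.ndarray
    info: np.ndarray
    converged: bool
    iterations: int
    names: list[str] = field(default_factory=list)

    def model_cov(self) -> np.ndarray:
        """Inverse (pseudo-)information.  Model-based covariance; for weighted
        fits this is not design-consistent (see the variance module)."""
        return np.linalg.inv(self.info)


# ---------------------------------------------------------------------------
# per-unit scores and observed information
# ---------------------------------------------------------------------------


def _softmax_pieces(family: ModelFamily, params: Parameters, X: np.ndarray):
    """Shared machinery for the two baseline-category-logit families."""
    m = family.K - 1
    s = X @ params.beta
    if family.name == "sm":
        coef = params.phi[:m]
        eta = params.alpha[None, :] + np.outer(s, coef)
    else:
        acc = np.cumsum(params.alpha[::-1])[::-1]
        coef = np.arange(m, 0, -1, dtype=float)
        eta = acc[None, :] + np.outer(s, coef)
    emax = np.maximum(eta.max(axis=1), 0.0)
    ee = np.exp(eta - emax[:, None])
    denom = np.exp(-emax) + ee.sum(axis=1)
    P = ee / denom[:, None]  # n x m, probabilities of categories 1..K-1
    return s, coef, P


def per_unit_scores(
    family: ModelFamily, params: Parameters, data: SampleData
) -> np.ndarray:
    """n x dim matrix of unweighted per-unit score vectors U_i."""
    y0 = data.y - 1
    X = data.X
    n, m, p = data.n, family.K - 1, family.p

    if family.name in ("sm", "ac"):
        s, coef, P = _softmax_pieces(family, params, X)
        G = -P.copy()
        low = y0 < m
        G[np.arange(n)[low], y0[low]] += 1.0
        if family.name == "sm":
            U = np.empty((n, family.n_params))
            U[:, :m] = G
            U[:, m : m + family.K - 2] = G[:, 1:m] * s[:, None]
            U[:, m + family.K - 2 :] = (G @ coef)[:, None] * X
        else:
            U = np.empty((n, family.n_params))
            U[:, :m] = np.cumsum(G, axis=1)
            U[:, m:] = (G @ coef)[:, None] * X
        return U

    if family.name == "cr":
        eta = params.alpha[None, :] + (X @ params.beta)[:, None]
        pk = expit(eta)
        ks = np.arange(m)
        r = (y0[:, None] >= ks[None, :]).astype(float)
        d = np.zeros((n, m))
        low = y0 < m
        d[np.arange(n)[low], y0[low]] = 1.0
        G = d - r * pk
        U = np.empty((n, family.n_params))
        U[:, :m] = G
        U[:, m:] = G.sum(axis=1)[:, None] * X
        return U

    # cm
    gamma, a, b, pi_y, ky, kb = _cm_pieces(family, params, data)
    U = np.zeros((n, family.n_params))
    idx = np.arange(n)
    has_a = ky < m
    has_b = kb >= 0
    U[idx[has_a], ky[has_a]] = (a / pi_y)[has_a]
    np.subtract.at(U, (idx[has_b], kb[has_b]), (b / pi_y)[has_b])
    U[:, m:] = ((a - b) / pi_y)[:, None] * X
    return U


def _cm_pieces(family: ModelFamily, params: Parameters, data: SampleData):
    m = family.K - 1
    if m > 1 and not np.all(np.diff(params.alpha) > 0):
        raise InvalidParameterError(
            "cumulative-logit intercepts must be strictly increasing"
        )
    s = data.X @ params.beta
    gamma = expit(params.alpha[None, :] + s[:, None])  # n x m
    y0 = data.y - 1
    n = data.n
    idx = np.arange(n)
    ky = y0  # index of gamma_y (valid when y0 < m)
    kb = y0 - 1  # index of gamma_{y-1} (valid when >= 0)
    g_hi = np.where(ky < m, gamma[idx, np.minimum(ky, m - 1)], 1.0)
    g_lo = np.where(kb >= 0, gamma[idx, np.maximum(kb, 0)], 0.0)
    pi_y = g_hi - g_lo
    if np.any(pi_y <= 0):
        raise InvalidParameterError("cumulative-logit probabilities are non-positive")
    a = np.where(ky < m, g_hi * (1.0 - g_hi), 0.0)
    b = np.where(kb >= 0, g_lo * (1.0 - g_lo), 0.0)
    return gamma, a, b, pi_y, ky, kb


def _moment_matrix(P: np.ndarray, mom: np.ndarray) -> np.ndarray:
    """sum_i mom_i * (diag(P_i) - P_i P_i')  for the softmax families."""
    Pm = P * mom[:, None]
    return np.diag(Pm.sum(axis=0)) - P.T @ Pm


def score_and_info(
    family: ModelFamily, params: Parameters, data: SampleData
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted total score and observed information of the pseudo-likelihood.

    Returns ``(sum_i w_i U_i, -sum_i w_i d2 l_i / d theta2)``.
    """
    w = data.w
    X = data.X
    n, m, p = data.n, family.K - 1, family.p
    dim = family.n_params
    U = per_unit_scores(family, params, data)
    score = U.T @ w

    info = np.zeros((dim, dim))

    if family.name == "sm":
        s, coef, P = _softmax_pieces(family, params, X)
        y0 = data.y - 1
        G = -P.copy()
        low = y0 < m
        G[np.arange(n)[low], y0[low]] += 1.0
        nfree = family.K - 2
        S1 = _moment_matrix(P, w)
        S2 = _moment_matrix(P, w * s)
        S3 = _moment_matrix(P, w * s * s)
        pphi = P @ coef
        u = P * coef[None, :] - P * pphi[:, None]  # rows W_i phi
        q = P @ (coef**2) - pphi**2
        wX = w[:, None] * X
        info[:m, :m] = S1
        info[:m, m : m + nfree] = S2[:, 1:m]
        info[m : m + nfree, :m] = S2[1:m, :]
        info[:m, m + nfree :] = u.T @ wX
        info[m + nfree :, :m] = info[:m, m + nfree :].T
        info[m : m + nfree, m : m + nfree] = S3[1:m, 1:m]
        # bilinear phi-beta block includes the second-derivative of eta term
        fb = ((w * s)[:, None] * u[:, 1:m]).T @ X - (w[:, None] * G[:, 1:m]).T @ X
        info[m : m + nfree, m + nfree :] = fb
        info[m + nfree :, m : m + nfree] = fb.T
        info[m + nfree :, m + nfree :] = X.T @ (X * (w * q)[:, None])
        return score, info

    if family.name == "ac":
        s, coef, P = _softmax_pieces(family, params, X)
        A = np.triu(np.ones((m, m)))  # d eta_k / d alpha_j = 1{j >= k}
        S1 = _moment_matrix(P, w)
        pc = P @ coef
        v = P * coef[None, :] - P * pc[:, None]
        q = P @ (coef**2) - pc**2
        wX = w[:, None] * X
        info[:m, :m] = A.T @ S1 @ A
        ab = A.T @ (v.T @ wX)
        info[:m, m:] = ab
        info[m:, :m] = ab.T
        info[m:, m:] = X.T @ (X * (w * q)[:, None])
        return score, info

    if family.name == "cr":
        eta = params.alpha[None, :] + (X @ params.beta)[:, None]
        pk = expit(eta)
        y0 = data.y - 1
        r = (y0[:, None] >= np.arange(m)[None, :]).astype(float)
        v = r * pk * (1.0 - pk)
        wv = w[:, None] * v
        info[:m, :m] = np.diag(wv.sum(axis=0))
        ab = wv.T @ X
        info[:m, m:] = ab
        info[m:, :m] = ab.T
        info[m:, m:] = X.T @ (X * (w * v.sum(axis=1))[:, None])
        return score, info

    # cm: per-unit Hessian in the eta space is 2x2 at (y, y-1)
    gamma, a, b, pi_y, ky, kb = _cm_pieces(family, params, data)
    idx = np.arange(n)
    g_hi = np.where(ky < m, gamma[idx, np.minimum(ky, m - 1)], 1.0)
    g_lo = np.where(kb >= 0, gamma[idx, np.maximum(kb, 0)], 0.0)
    a2 = a * (1.0 - 2.0 * g_hi)
    b2 = b * (1.0 - 2.0 * g_lo)
    Haa = np.where(ky < m, a2 / pi_y - (a / pi_y) ** 2, 0.0)
    Hbb = np.where(kb >= 0, -b2 / pi_y - (b / pi_y) ** 2, 0.0)
    Hab = np.where((ky < m) & (kb >= 0), a * b / pi_y**2, 0.0)
    wHaa, wHbb, wHab = w * Haa, w * Hbb, w * Hab
    Iaa = np.zeros((m, m))
    mask_a = ky < m
    np.subtract.at(Iaa, (ky[mask_a], ky[mask_a]), wHaa[mask_a])
    mask_b = kb >= 0
    np.subtract.at(Iaa, (kb[mask_b], kb[mask_b]), wHbb[mask_b])
    mask_ab = mask_a & mask_b
    np.subtract.at(Iaa, (ky[mask_ab], kb[mask_ab]), wHab[mask_ab])
    np.subtract.at(Iaa, (kb[mask_ab], ky[mask_ab]), wHab[mask_ab])
    info[:m, :m] = Iaa
    # row sums of the per-unit eta-Hessian feed the alpha-beta block
    row_hi = wHaa + wHab  # attaches to index ky
    row_lo = wHbb + wHab  # attaches to index kb
    Iab = np.zeros((m, p))
    for k in range(m):
        sel = mask_a & (ky == k)
        if sel.any():
            Iab[k] -= row_hi[sel] @ X[sel]
        sel = mask_b & (kb == k)
        if sel.any():
            Iab[k] -= row_lo[sel] @ X[sel]
    info[:m, m:] = Iab
    info[m:, :m] = Iab.T
    tot = wHaa + wHbb + 2.0 * wHab
    info[m:, m:] = -(X.T @ (X * tot[:, None]))
    return score, info


# ---------------------------------------------------------------------------
# initial values
# ---------------------------------------------------------------------------


def _initial_params(family: ModelFamily, data: SampleData) -> Parameters:
    K, m = family.K, family.K - 1
    wsum = np.array(
        [data.w[data.y == k].sum() for k in range(1, K + 1)], dtype=float
    )
    pk = np.clip(wsum / wsum.sum(), 1e-6, None)
    pk = pk / pk.sum()
    beta = np.zeros(family.p)
    if family.name == "ac":
        alpha = np.log(pk[:m] / pk[1:])
        return Parameters(alpha, beta)
    if family.name == "cr":
        tail = np.cumsum(pk[::-1])[::-1]
        alpha = np.log(pk[:m] / tail[1:])
        return Parameters(alpha, beta)
    if family.name == "cm":
        cum = np.cumsum(pk)[:m]
        alpha = np.log(cum / (1.0 - cum))
        return Parameters(alpha, beta)
    # sm: neutral equally spaced scores; beta must be perturbed away from 0
    # because phi is unidentified at beta = 0 (handled by the ac warm start
    # in fit(); this is only the fallback)
    alpha = np.log(pk[:m] / pk[-1])
    phi = np.arange(K - 1, -1, -1, dtype=float) / (K - 1)
    return Parameters(alpha, np.full(family.p, 0.01), phi)


def _is_valid(family: ModelFamily, theta: np.ndarray) -> bool:
    if family.name != "cm" or family.K == 2:
        return True
    alpha = theta[: family.K - 1]
    return bool(np.all(np.diff(alpha) > 0))


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def fit(
    family: ModelFamily,
    data: SampleData,
    *,
    init: Parameters | None = None,
    tol: float = 1e-10,
    gtol: float = 1e-6,
    max_iter: int = 200,
) -> FitResult:
    """Maximise the weighted log pseudo-likelihood by damped Newton steps.

    Deterministic given the data and options.  Non-convergence is reported
    via ``FitResult.converged`` plus a warning, not an exception.
    """
    observed = np.unique(data.y)
    missing = sorted(set(range(1, family.K + 1)) - set(observed.tolist()))
    if missing:
        raise ValueError(f"outcome categories {missing} are not observed in the data")
    if np.any((observed < 1) | (observed > family.K)):
        raise ValueError(f"outcome values outside 1..{family.K}")
    if data.p != family.p:
        raise ValueError(f"data has {data.p} covariates, family expects {family.p}")

    if init is not None:
        theta = pack(family, init)
    elif family.name == "sm" and family.K >= 3:
        # warm start from the adjacent-category fit re-expressed as a
        # stereotype model (equally spaced scores, rescaled slopes)
        ac_fit = fit(
            ModelFamily("ac", family.K, family.p), data,
            tol=tol, gtol=gtol, max_iter=max_iter,
        )
        theta = pack(family, ac_as_sm(ac_fit.params, family.K))
        if family.p and np.all(np.abs(ac_fit.params.beta) < 1e-8):
            # phi unidentified when beta == 0; nudge
            theta[-family.p :] = 1e-3
    else:
        theta = pack(family, _initial_params(family, data))

    def objective(th: np.ndarray) -> float:
        return float(
            data.w @ loglik_contributions(family, unpack(family, th), data.y, data.X)
        )

    ll = objective(theta)
    converged = False
    it = 0
    score, info = score_and_info(family, unpack(family, theta), data)
    scale = np.trace(info) / family.n_params

    for it in range(1, max_iter + 1):
        lam = 0.0
        accepted = False
        for _ in range(12):
            try:
                step = np.linalg.solve(
                    info + lam * scale * np.eye(family.n_params), score
                )
            except np.linalg.LinAlgError:
                lam = max(lam * 10.0, 1e-8)
                continue
            t = 1.0
            for _ in range(40):
                cand = theta + t * step
                if _is_valid(family, cand):
                    try:
                        cand_ll = objective(cand)
                    except InvalidParameterError:
                        cand_ll = -np.inf
                    if np.isfinite(cand_ll) and cand_ll >= ll:
                        accepted = True
                        break
                t *= 0.5
            if accepted:
                break
            lam = max(lam * 10.0, 1e-6)
        if not accepted:
            break
        delta = cand_ll - ll
        step_size = np.max(np.abs(t * step)) / (1.0 + np.max(np.abs(theta)))
        theta, ll = cand, cand_ll
        score, info = score_and_info(family, unpack(family, theta), data)
        scale = np.trace(info) / family.n_params
        if (
            delta <= tol * (1.0 + abs(ll))
            and step_size <= 1e-8
            and np.max(np.abs(score)) <= gtol * max(1.0, abs(ll))
        ):
            converged = True
            break
    else:
        it = max_iter

    if not converged and np.max(np.abs(score)) <= gtol * max(1.0, abs(ll)):
        converged = True
    if converged and np.max(np.abs(theta)) > 50.0:
        # score can vanish while estimates run off to +-inf (separation)
        converged = False
    if not converged:
        warnings.warn(
            f"{family.name} fit did not converge after {it} iterations "
            f"(max |score| = {np.max(np.abs(score)):.3g})",
            NonConvergenceWarning,
            stacklevel=2,
        )

    return FitResult(
        family=family,
        params=unpack(family, theta),
        theta=theta,
        loglik=ll,
        score=score,
        info=info,
        converged=converged,
        iterations=it,
        names=param_names(family),
    )
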