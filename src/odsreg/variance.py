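"""Model-based and design-based (linearization) covariance estimation.

The design-based estimator approximates the sampling variance of the
weighted estimator by the variance of the weighted total of the per-unit
influence functions ``z_i = I_w^{-1} U_i``.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .estimation import FitResult, SampleData, per_unit_scores

__all__ = [
    "CovarianceResult",
    "influence_functions",
    "design_cov",
    "covariance",
    "delta_phi_beta",
]


@dataclass
class CovarianceResult:
    model_based: np.ndarray
    design_based: np.ndarray
    se_model: np.ndarray
    se_design: np.ndarray
    names: list[str]


def influence_functions(fit: FitResult, data: SampleData) -> np.ndarray:
    """n x dim matrix of influence functions ``z_i = I_w^{-1} U_i``.

    Raises if the fitted information is singular, naming the parameter whose
    curvature vanishes.
    """
    U = per_unit_scores(fit.family, fit.params, data)
    diag = np.diag(fit.info)
    if np.any(diag <= 0) or not np.isfinite(np.linalg.cond(fit.info)) or (
        np.linalg.cond(fit.info) > 1e12
    ):
        worst = fit.names[int(np.argmin(diag))] if fit.names else str(np.argmin(diag))
        raise np.linalg.LinAlgError(
            f"information matrix is singular or ill-conditioned (parameter {worst})"
        )
    return np.linalg.solve(fit.info, U.T).T


def design_cov(
    influence: np.ndarray,
    data: SampleData,
    design: str = "wr",
    fpc: bool = False,
    n_k: np.ndarray | None = None,
    f_k: np.ndarray | None = None,
) -> np.ndarray:
    """Linearization covariance of the weighted estimator.

    ``design='wr'`` (default) treats the weighted influence totals as a
    with-replacement sample: ``n/(n-1) * sum_i (w_i z_i - mbar)(...)'``.
    ``design='stratified'`` computes within-outcome-category deviations with
    ``n_k/(n_k - 1)`` factors and an optional ``(1 - f_k)`` finite-population
    correction (requires ``f_k``).
    """
    wz = data.w[:, None] * influence
    n = len(wz)
    if design == "wr":
        dev = wz - wz.mean(axis=0)
        return n / (n - 1) * dev.T @ dev
    if design != "stratified":
        raise ValueError(f"unknown design {design!r}")
    V = np.zeros((wz.shape[1], wz.shape[1]))
    cats = np.unique(data.y)
    for j, k in enumerate(cats):
        sel = data.y == k
        nk = int(sel.sum())
        if nk < 2:
            raise ValueError(f"outcome category {k} has fewer than 2 sampled units")
        dev = wz[sel] - wz[sel].mean(axis=0)
        factor = nk / (nk - 1)
        if fpc:
            if f_k is None:
                raise ValueError("fpc=True requires sampling fractions f_k")
            factor *= 1.0 - f_k[j]
        V += factor * dev.T @ dev
    return V


def covariance(
    fit: FitResult,
    data: SampleData,
    design: str = "wr",
    fpc: bool = False,
    f_k: np.ndarray | None = None,
) -> CovarianceResult:
    """Bundle model-based and design-based covariances with their SEs."""
    model = fit.model_cov()
    z = influence_functions(fit, data)
    dsgn = design_cov(z, data, design=design, fpc=fpc, f_k=f_k)
    return CovarianceResult(
        model_based=model,
        design_based=dsgn,
        se_model=np.sqrt(np.diag(model)),
        se_design=np.sqrt(np.diag(dsgn)),
        names=list(fit.names),
    )


def delta_phi_beta(
    fit: FitResult, cov: np.ndarray
) -> list[dict]:
    """Delta-method estimates and SEs of the products ``phi_k * beta_j``.

    ``cov`` is a covariance matrix of the free parameter vector (either the
    model-based or design-based one).  ``phi_1`` is fixed at 1 so the k=1
    entry inherits the slope's SE; ``phi_K`` is fixed at 0 so the k=K entry
    is identically zero.
    """
    if fit.family.name != "sm":
        raise ValueError("phi*beta products are defined only for the stereotype model")
    K, p, m = fit.family.K, fit.family.p, fit.family.K - 1
    phi = fit.params.phi
    beta = fit.params.beta
    out = []
    for j in range(p):
        jb = m + (K - 2) + j  # index of beta_j in the free vector
        vb = cov[jb, jb]
        for k in range(1, K + 1):
            if k == 1:
                est, var = beta[j], vb
            elif k == K:
                est, var = 0.0, 0.0
            else:
                jf = m + (k - 2)  # index of phi_k
                vf = cov[jf, jf]
                cfb = cov[jf, jb]
                est = phi[k - 1] * beta[j]
                var = (
                    phi[k - 1] ** 2 * vb
                    + beta[j] ** 2 * vf
                    + 2.0 * phi[k - 1] * beta[j] * cfb
                )
            out.append(
                {
                    "k": k,
                    "j": j + 1,
                    "name": f"phi{k}beta{j + 1}",
                    "estimate": float(est),
                    "se": float(np.sqrt(max(var, 0.0))),
                }
            )
    return out
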