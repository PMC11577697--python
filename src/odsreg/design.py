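"""Outcome-dependent sampling: drawing samples, weights, and the analytic
relationship between cohort-model and sampled-model parameters.

Sampling ``n_k`` units from each outcome category of a cohort is stratified
sampling with strata defined by the outcome; inclusion probabilities are
``f_k = n_k / N_k`` and the survey weights are their inverses.  For the
stereotype and adjacent-category families the sampled data follow the same
family with intercepts offset by ``ln(f_k / f_K)`` on the baseline-logit
scale; no such closed form exists for the continuation-ratio or cumulative
families (except the continuation-ratio special case ``f_2 = ... = f_K``).
"""
from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .estimation import SampleData
from .families import ModelFamily, Parameters, category_probs

__all__ = [
    "ODSDesign",
    "sample_ods",
    "sampled_intercepts",
    "sampled_probs",
    "reweight_probs",
    "cr_special_case_check",
    "weight_cv",
]


@dataclass
class ODSDesign:
    """Realized outcome-dependent sampling design."""

    K: int
    N_k: np.ndarray
    n_k: np.ndarray
    seed: int | None = None

    def __post_init__(self) -> None:
        self.N_k = np.asarray(self.N_k, dtype=int)
        self.n_k = np.asarray(self.n_k, dtype=int)
        if self.N_k.shape != (self.K,) or self.n_k.shape != (self.K,):
            raise ValueError("N_k and n_k must have length K")
        if np.any(self.n_k <= 0) or np.any(self.n_k > self.N_k):
            raise ValueError("need 0 < n_k <= N_k in every category")

    @property
    def f_k(self) -> np.ndarray:
        return self.n_k / self.N_k

    @property
    def N(self) -> int:
        return int(self.N_k.sum())

    @property
    def n(self) -> int:
        return int(self.n_k.sum())

    def to_json(self) -> str:
        return json.dumps(
            {
                "K": self.K,
                "N_k": self.N_k.tolist(),
                "n_k": self.n_k.tolist(),
                "f_k": self.f_k.tolist(),
                "seed": self.seed,
            }
        )


def sample_ods(
    cohort: SampleData,
    n_k: np.ndarray | list[int] | int,
    seed: int | np.random.Generator | None = None,
) -> tuple[SampleData, ODSDesign]:
    """Sample ``n_k`` units per outcome category without replacement.

    Weights ``N_k / n_k`` are computed from the realized cohort category
    counts.  Deterministic given the seed.
    """
    K = cohort.observed_K()
    if np.isscalar(n_k):
        n_k = np.full(K, int(n_k))
    n_k = np.asarray(n_k, dtype=int)
    if n_k.shape != (K,):
        raise ValueError(f"n_k must have length {K}")
    N_k = np.array([(cohort.y == k).sum() for k in range(1, K + 1)])
    short = np.nonzero(n_k > N_k)[0]
    if short.size:
        k = short[0] + 1
        raise ValueError(
            f"outcome category {k} has only {N_k[k - 1]} cohort units, "
            f"cannot sample {n_k[k - 1]}"
        )
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    picked = []
    for k in range(1, K + 1):
        idx = np.nonzero(cohort.y == k)[0]
        picked.append(rng.choice(idx, size=n_k[k - 1], replace=False))
    idx = np.concatenate(picked)
    w = (N_k / n_k)[cohort.y[idx] - 1].astype(float)
    data = SampleData(cohort.y[idx], cohort.X[idx], w)
    design = ODSDesign(
        K=K, N_k=N_k, n_k=n_k, seed=seed if isinstance(seed, int) else None
    )
    return data, design


def sampled_intercepts(
    family: ModelFamily, params: Parameters, f: np.ndarray
) -> Parameters:
    """Parameters of the model followed by the sampled data.

    Slopes (and stereotype scores) are unchanged; intercepts are shifted by
    ``ln(f_k / f_K)`` on the baseline-logit scale.  For the adjacent-category
    parameterization the shift is applied to the reverse-cumulative-sum
    representation and mapped back, giving per-category offsets
    ``ln(f_k / f_{k+1})``.
    """
    f = np.asarray(f, dtype=float)
    if f.shape != (family.K,):
        raise ValueError(f"f must have length {family.K}")
    if np.any(f <= 0):
        raise ValueError("sampling fractions must be positive")
    out = params.copy()
    if family.name == "sm":
        out.alpha = params.alpha + np.log(f[:-1] / f[-1])
        return out
    if family.name == "ac":
        out.alpha = params.alpha + np.log(f[:-1] / f[1:])
        return out
    raise ValueError(
        f"no closed-form sampled-model parameters exist for family "
        f"{family.name!r} under outcome-dependent sampling"
    )


def reweight_probs(P: np.ndarray, f: np.ndarray) -> np.ndarray:
    """Bayes reweighting of a probability matrix: ``f_k pi_k / sum_h f_h pi_h``."""
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0):
        raise ValueError("sampling fractions must be positive")
    num = P * f[None, :]
    return num / num.sum(axis=1, keepdims=True)


def sampled_probs(
    family: ModelFamily, params: Parameters, f: np.ndarray, X: np.ndarray
) -> np.ndarray:
    """Category probabilities conditional on inclusion in the sample."""
    return reweight_probs(category_probs(family, params, X), f)


def cr_special_case_check(f: np.ndarray, atol: float = 1e-12) -> bool:
    """True iff ``f_2 = ... = f_K``, the only case in which the sampled data
    from a continuation-ratio model follow a continuation-ratio model (with
    just the first intercept shifted)."""
    f = np.asarray(f, dtype=float)
    if len(f) < 2:
        return True
    return bool(np.all(np.abs(f[1:] - f[1]) <= atol))


def weight_cv(w: np.ndarray) -> float:
    """Coefficient of variation (population SD / mean) of the weights."""
    w = np.asarray(w, dtype=float)
    return float(w.std() / w.mean())
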