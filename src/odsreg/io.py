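"""Delimited-text data I/O and JSON serialization of results."""
from __future__ import annotations

import json
from typing import Sequence

import numpy as np
import pandas as pd

from .estimation import FitResult, SampleData
from .families import Parameters

__all__ = ["read_table", "write_table", "fit_report", "params_to_dict", "params_from_dict"]


def read_table(
    path,
    outcome_col: str,
    covariate_cols: Sequence[str],
    weight_col: str | None = None,
    level_order: Sequence[str] | None = None,
    sep: str = ",",
) -> SampleData:
    """Read a delimited text file with a header into a SampleData.

    The outcome column must be integer-coded 1..K, or hold ordered labels
    with ``level_order`` supplying the ordering (coded 1..K in that order).
    """
    df = pd.read_csv(path, sep=sep)
    cols = [outcome_col, *covariate_cols] + ([weight_col] if weight_col else [])
    missing_cols = [c for c in cols if c not in df.columns]
    if missing_cols:
        raise ValueError(f"columns not found: {missing_cols}")
    sub = df[cols]
    bad = sub.isna().any(axis=1)
    if bad.any():
        rows = (np.nonzero(bad.to_numpy())[0] + 2).tolist()  # 1-based + header
        raise ValueError(f"missing values in used columns at file rows {rows[:20]}")

    raw = df[outcome_col]
    if level_order is not None:
        mapping = {lvl: i + 1 for i, lvl in enumerate(level_order)}
        unknown = set(raw.astype(str)) - set(map(str, mapping))
        if unknown:
            raise ValueError(f"outcome labels {sorted(unknown)} not in level_order")
        y = raw.astype(str).map({str(k): v for k, v in mapping.items()}).to_numpy()
    else:
        y = raw.to_numpy()
        if not np.all(y == np.round(np.asarray(y, dtype=float))):
            raise ValueError(
                "outcome column is not integer-coded; pass level_order for labels"
            )
        y = np.asarray(y, dtype=int)
        if y.min() < 1:
            raise ValueError("integer outcomes must start at 1")

    X = df[list(covariate_cols)].to_numpy(dtype=float)
    w = None
    if weight_col:
        w = df[weight_col].to_numpy(dtype=float)
        if np.any(w <= 0):
            raise ValueError("weight column contains non-positive values")
    return SampleData(y, X, w)


def write_table(
    data: SampleData,
    path,
    outcome_col: str = "y",
    covariate_cols: Sequence[str] | None = None,
    weight_col: str | None = "w",
) -> None:
    cols = covariate_cols or [f"x{j + 1}" for j in range(data.p)]
    df = pd.DataFrame(data.X, columns=list(cols))
    df.insert(0, outcome_col, data.y)
    if weight_col:
        df[weight_col] = data.w
    df.to_csv(path, index=False)


def params_to_dict(params: Parameters) -> dict:
    out = {"alpha": params.alpha.tolist(), "beta": params.beta.tolist()}
    if params.phi is not None:
        out["phi"] = params.phi.tolist()
    return out


def params_from_dict(d: dict) -> Parameters:
    return Parameters(
        np.asarray(d["alpha"], dtype=float),
        np.asarray(d["beta"], dtype=float),
        None if d.get("phi") is None else np.asarray(d["phi"], dtype=float),
    )


def fit_report(
    fit: FitResult,
    se_model: np.ndarray | None = None,
    se_design: np.ndarray | None = None,
    cov_model: np.ndarray | None = None,
    cov_design: np.ndarray | None = None,
    phi_beta: list[dict] | None = None,
    extra: dict | None = None,
) -> str:
    """Full-precision JSON fit report."""
    body: dict = {
        "family": fit.family.name,
        "K": fit.family.K,
        "p": fit.family.p,
        "converged": bool(fit.converged),
        "iterations": fit.iterations,
        "loglik": fit.loglik,
        "names": fit.names,
        "estimates": fit.theta.tolist(),
        "params": params_to_dict(fit.params),
    }
    if se_model is not None:
        body["se_model"] = np.asarray(se_model).tolist()
    if se_design is not None:
        body["se_design"] = np.asarray(se_design).tolist()
    if cov_model is not None:
        body["cov_model"] = np.asarray(cov_model).tolist()
    if cov_design is not None:
        body["cov_design"] = np.asarray(cov_design).tolist()
    if phi_beta is not None:
        body["phi_beta"] = phi_beta
    if extra:
        body.update(extra)
    return json.dumps(body, indent=2)
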