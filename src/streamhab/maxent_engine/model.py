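"""L1-regularized maximum-entropy fitting and prediction.

The model estimates a Gibbs distribution over background cells,
``raw(x) = exp(f(x)·λ) / Z``, by minimizing the regularized negative
log-likelihood of the presences

    J(λ) = −mean_presence(f·λ) + log Σ_background exp(f·λ)
           + Σ_j rm·β_j·|λ_j|

which is convex; the L1 term is handled exactly by splitting each
coefficient into a positive and a negative part and running bounded
L-BFGS.  The familiar suitability output is the complementary log-log
transform ``1 − exp(−e^H · raw)`` with ``H`` the entropy of the raw
distribution over background.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp

from ..raster_core import Grid
from .features import FeatureSet

__all__ = ["MaxentModel", "fit", "predict_rows", "predict"]

_ZERO_TOL = 1e-7  # coefficients below this magnitude count as exactly zero


@dataclasses.dataclass
class MaxentModel:
    features: FeatureSet
    lam: np.ndarray  # coefficients, one per feature
    rm: float  # regularization multiplier used in the fit
    log_z: float  # log Σ_background exp(f·λ)
    entropy: float  # H of the raw distribution over background
    n_presence: int
    converged: bool = True

    @property
    def k(self) -> int:
        """Number of nonzero coefficients (AICc parameter count)."""
        return int(np.sum(np.abs(self.lam) > _ZERO_TOL))

    def linear_predictor(self, values: pd.DataFrame) -> np.ndarray:
        return self.features.transform(values) @ self.lam

    def log_raw(self, values: pd.DataFrame) -> np.ndarray:
        return self.linear_predictor(values) - self.log_z

    def raw(self, values: pd.DataFrame) -> np.ndarray:
        """exp(f·λ)/Z — relative occurrence rate, normalized over background."""
        return np.exp(self.log_raw(values))

    def cloglog(self, values: pd.DataFrame) -> np.ndarray:
        return 1.0 - np.exp(-np.exp(self.entropy) * self.raw(values))

    # -- serialization ----------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        doc = {
            "features": self.features.to_dict(),
            "lam": self.lam.tolist(),
            "rm": self.rm,
            "log_z": self.log_z,
            "entropy": self.entropy,
            "n_presence": self.n_presence,
            "converged": self.converged,
        }
        Path(path).write_text(json.dumps(doc))

    @staticmethod
    def from_json(path: str | Path) -> "MaxentModel":
        doc = json.loads(Path(path).read_text())
        return MaxentModel(
            features=FeatureSet.from_dict(doc["features"]),
            lam=np.asarray(doc["lam"], dtype=float),
            rm=doc["rm"],
            log_z=doc["log_z"],
            entropy=doc["entropy"],
            n_presence=doc["n_presence"],
            converged=doc["converged"],
        )


def _objective_parts(
    lam: np.ndarray, mean_pres: np.ndarray, bg: np.ndarray
) -> tuple[float, np.ndarray]:
    eta = bg @ lam
    lse = logsumexp(eta)
    p = np.exp(eta - lse)
    value = -float(mean_pres @ lam) + float(lse)
    grad = -mean_pres + bg.T @ p
    return value, grad


def fit(
    features: FeatureSet,
    presence_values: pd.DataFrame,
    background_values: pd.DataFrame,
    rm: float = 1.0,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> MaxentModel:
    """Fit coefficients by convex optimization (split-variable L-BFGS-B).

    Raises ``RuntimeError`` with optimizer diagnostics on non-convergence.
    """
    if len(presence_values) < 2:
        raise ValueError("need at least 2 presences")
    X_pres = features.transform(presence_values)
    X_bg = features.transform(background_values)
    mean_pres = X_pres.mean(axis=0)
    penal = rm * features.betas
    nf = len(features)

    def fun(z: np.ndarray) -> tuple[float, np.ndarray]:
        lam = z[:nf] - z[nf:]
        value, grad = _objective_parts(lam, mean_pres, X_bg)
        value += float(penal @ (z[:nf] + z[nf:]))
        return value, np.concatenate([grad + penal, -grad + penal])

    res = minimize(
        fun,
        np.zeros(2 * nf),
        jac=True,
        method="L-BFGS-B",
        bounds=[(0.0, None)] * (2 * nf),
        options={"maxiter": max_iter, "ftol": 1e-12, "gtol": tol},
    )
    if not res.success and "ABNORMAL" in str(res.message).upper():
        raise RuntimeError(f"optimizer failed: {res.message} (nit={res.nit})")
    lam = res.x[:nf] - res.x[nf:]
    lam[np.abs(lam) < _ZERO_TOL] = 0.0
    eta_bg = X_bg @ lam
    log_z = float(logsumexp(eta_bg))
    p = np.exp(eta_bg - log_z)
    entropy = float(-np.sum(p * np.log(np.maximum(p, 1e-300))))
    return MaxentModel(
        features=features,
        lam=lam,
        rm=rm,
        log_z=log_z,
        entropy=entropy,
        n_presence=len(presence_values),
        converged=bool(res.success),
    )


def predict_rows(
    model: MaxentModel, values: pd.DataFrame, output: str = "cloglog"
) -> np.ndarray:
    if output == "raw":
        return model.raw(values)
    if output == "cloglog":
        return model.cloglog(values)
    raise ValueError(f"unknown output {output!r}")


def predict(
    model: MaxentModel,
    stack,
    output: str = "cloglog",
    block: int = 20000,
) -> Grid:
    """Predict over a covariate stack, block-wise to bound memory.

    Cells with any nodata covariate become nodata.  Values outside the
    training range are clamped by the feature transform.
    """
    names = stack.names
    ref = stack[names[0]]
    valid = np.ones(ref.shape, dtype=bool)
    for name in names:
        valid &= stack[name].valid()
    rows, cols = np.nonzero(valid)
    out = np.full(ref.shape, ref.nodata, dtype=float)
    for start in range(0, len(rows), block):
        r = rows[start : start + block]
        c = cols[start : start + block]
        vals = stack.sample(r, c)
        out[r, c] = predict_rows(model, vals, output=output)
    return ref.copy_with(out, kind="continuous")
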