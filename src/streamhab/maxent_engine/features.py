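"""Feature expansion for the maximum-entropy model.

Continuous covariates are min-max scaled to [0, 1] using the pooled
presence+background range, then expanded into linear, quadratic,
product, and hinge features; a categorical covariate becomes one
indicator per observed class.  All features live in [0, 1] so a single
per-class regularization weight is meaningful.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

__all__ = ["Feature", "FeatureSet", "make_features"]

# default per-feature-class regularization weights; the linear/quadratic/
# product weight additionally shrinks with presence sample size m as c/sqrt(m)
BETA_DEFAULTS = {"hinge": 0.5, "categorical": 0.25, "lqp_constant": 1.0, "lqp_floor": 0.05}


@dataclasses.dataclass
class Feature:
    """One column of the design matrix."""

    kind: str  # linear | quadratic | product | hinge_fwd | hinge_rev | indicator
    var: str
    var2: str | None = None  # second variable of a product
    knot: float | None = None  # hinge knot (raw variable units)
    level: int | None = None  # class code of an indicator

    @property
    def label(self) -> str:
        if self.kind == "product":
            return f"{self.var}*{self.var2}"
        if self.kind in ("hinge_fwd", "hinge_rev"):
            return f"{self.kind}({self.var}@{self.knot:.6g})"
        if self.kind == "indicator":
            return f"{self.var}=={self.level}"
        if self.kind == "quadratic":
            return f"{self.var}^2"
        return self.var


class FeatureSet:
    """Feature definitions plus the normalization needed to apply them."""

    def __init__(
        self,
        features: list[Feature],
        ranges: dict[str, tuple[float, float]],
        betas: np.ndarray,
        categorical: dict[str, list[int]],
    ):
        self.features = features
        self.ranges = ranges
        self.betas = np.asarray(betas, dtype=float)
        self.categorical = categorical

    def __len__(self) -> int:
        return len(self.features)

    @property
    def labels(self) -> list[str]:
        return [f.label for f in self.features]

    def variable_of(self, j: int) -> str:
        return self.features[j].var

    @property
    def variables(self) -> list[str]:
        seen: list[str] = []
        for f in self.features:
            for v in (f.var, f.var2):
                if v is not None and v not in seen:
                    seen.append(v)
        return seen

    def _scaled(self, values: pd.DataFrame, var: str) -> np.ndarray:
        lo, hi = self.ranges[var]
        x = values[var].to_numpy(float)
        if hi == lo:
            return np.zeros_like(x)
        return np.clip((x - lo) / (hi - lo), 0.0, 1.0)

    def transform(self, values: pd.DataFrame) -> np.ndarray:
        """Design matrix (n_rows × n_features), all entries in [0, 1].

        Continuous values outside the training range are clamped.
        """
        n = len(values)
        out = np.empty((n, len(self.features)), dtype=float)
        scaled_cache: dict[str, np.ndarray] = {}

        def scaled(var: str) -> np.ndarray:
            if var not in scaled_cache:
                scaled_cache[var] = self._scaled(values, var)
            return scaled_cache[var]

        for j, f in enumerate(self.features):
            if f.kind == "linear":
                out[:, j] = scaled(f.var)
            elif f.kind == "quadratic":
                out[:, j] = scaled(f.var) ** 2
            elif f.kind == "product":
                out[:, j] = scaled(f.var) * scaled(f.var2)
            elif f.kind == "hinge_fwd":
                lo, hi = self.ranges[f.var]
                x = values[f.var].to_numpy(float)
                denom = max(hi - f.knot, np.finfo(float).tiny)
                out[:, j] = np.clip((x - f.knot) / denom, 0.0, 1.0)
            elif f.kind == "hinge_rev":
                lo, hi = self.ranges[f.var]
                x = values[f.var].to_numpy(float)
                denom = max(f.knot - lo, np.finfo(float).tiny)
                out[:, j] = np.clip((f.knot - x) / denom, 0.0, 1.0)
            elif f.kind == "indicator":
                out[:, j] = (values[f.var].to_numpy() == f.level).astype(float)
            else:  # pragma: no cover
                raise ValueError(f"unknown feature kind {f.kind!r}")
        return out

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "features": [dataclasses.asdict(f) for f in self.features],
            "ranges": {k: list(v) for k, v in self.ranges.items()},
            "betas": self.betas.tolist(),
            "categorical": self.categorical,
        }

    @staticmethod
    def from_dict(d: dict) -> "FeatureSet":
        return FeatureSet(
            features=[Feature(**f) for f in d["features"]],
            ranges={k: tuple(v) for k, v in d["ranges"].items()},
            betas=np.asarray(d["betas"], dtype=float),
            categorical={k: list(v) for k, v in d["categorical"].items()},
        )


def make_features(
    values: pd.DataFrame,
    n_presence: int,
    classes: str = "LQHP",
    categorical_vars: tuple[str, ...] = ("landform",),
    n_hinge: int = 50,
    beta_constants: dict | None = None,
) -> FeatureSet:
    """Build a :class:`FeatureSet` from pooled presence+background values.

    ``classes`` is any subset of ``"LQHP"``.  Constant continuous
    variables are dropped.  Hinge knots sit at empirical quantiles
    strictly inside each variable's range; both forward and reverse
    hinges are generated.  The categorical variable always contributes
    indicator features when present.
    """
    if not classes or any(ch not in "LQHP" for ch in classes):
        raise ValueError("classes must be a non-empty subset of 'LQHP'")
    consts = dict(BETA_DEFAULTS)
    consts.update(beta_constants or {})
    m = max(n_presence, 1)
    beta_lqp = max(consts["lqp_floor"], consts["lqp_constant"] / np.sqrt(m))

    cont = [
        c
        for c in values.columns
        if c not in categorical_vars and values[c].to_numpy(float).std() > 0
    ]
    ranges = {
        c: (float(values[c].min()), float(values[c].max())) for c in cont
    }
    feats: list[Feature] = []
    betas: list[float] = []

    if "L" in classes:
        for v in cont:
            feats.append(Feature("linear", v))
            betas.append(beta_lqp)
    if "Q" in classes:
        for v in cont:
            feats.append(Feature("quadratic", v))
            betas.append(beta_lqp)
    if "P" in classes:
        for i, a in enumerate(cont):
            for b in cont[i + 1 :]:
                feats.append(Feature("product", a, var2=b))
                betas.append(beta_lqp)
    if "H" in classes:
        qs = np.linspace(0, 1, n_hinge + 2)[1:-1]
        for v in cont:
            x = values[v].to_numpy(float)
            knots = np.unique(np.quantile(x, qs))
            lo, hi = ranges[v]
            knots = knots[(knots > lo) & (knots < hi)]
            for k in knots:
                feats.append(Feature("hinge_fwd", v, knot=float(k)))
                betas.append(consts["hinge"])
                feats.append(Feature("hinge_rev", v, knot=float(k)))
                betas.append(consts["hinge"])

    categorical: dict[str, list[int]] = {}
    for v in categorical_vars:
        if v not in values.columns:
            continue
        levels = sorted(int(c) for c in np.unique(values[v].to_numpy()))
        categorical[v] = levels
        for lev in levels:
            feats.append(Feature("indicator", v, level=lev))
            betas.append(consts["categorical"])
    return FeatureSet(feats, ranges, np.asarray(betas), categorical)
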