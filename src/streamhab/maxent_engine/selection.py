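"""AICc model selection and k-fold cross-validation."""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .features import make_features
from .model import MaxentModel, fit

__all__ = [
    "ModelSelectionRecord",
    "aicc",
    "select_model",
    "CrossValidation",
    "crossvalidate",
]


@dataclasses.dataclass
class ModelSelectionRecord:
    rm: float
    classes: str
    k: int
    log_likelihood: float
    aicc: float | None  # None when n_presences <= k + 1


def aicc(
    model: MaxentModel,
    presence_values: pd.DataFrame,
    landscape_values: pd.DataFrame,
) -> ModelSelectionRecord:
    """Small-sample AIC of a fitted model.

    Raw predictions are renormalized to sum to one over the evaluation
    landscape (here: the supplied landscape rows, typically the background
    sample), the presence log-likelihood is summed, and
    ``AICc = 2k − 2logL + 2k(k+1)/(n−k−1)`` with ``k`` the count of
    nonzero coefficients.  Undefined (None) when ``n ≤ k+1``.
    """
    from scipy.special import logsumexp

    log_raw_pres = model.log_raw(presence_values)
    log_norm = logsumexp(model.log_raw(landscape_values))
    logl = float(np.sum(log_raw_pres - log_norm))
    k = model.k
    n = len(presence_values)
    if n <= k + 1:
        return ModelSelectionRecord(model.rm, _classes_of(model), k, logl, None)
    val = 2 * k - 2 * logl + 2 * k * (k + 1) / (n - k - 1)
    return ModelSelectionRecord(model.rm, _classes_of(model), k, logl, val)


def _classes_of(model: MaxentModel) -> str:
    kinds = {f.kind for f in model.features.features}
    out = ""
    if "linear" in kinds:
        out += "L"
    if "quadratic" in kinds:
        out += "Q"
    if "hinge_fwd" in kinds or "hinge_rev" in kinds:
        out += "H"
    if "product" in kinds:
        out += "P"
    return out


def select_model(
    presence_values: pd.DataFrame,
    background_values: pd.DataFrame,
    rms: tuple[float, ...] = (0.5, 1.0, 2.0),
    class_sets: tuple[str, ...] = ("L", "LQ", "LQH", "LQHP"),
    categorical_vars: tuple[str, ...] = ("landform",),
    n_hinge: int = 50,
) -> tuple[MaxentModel, list[ModelSelectionRecord]]:
    """Fit every (rm, feature classes) candidate and return the lowest-AICc
    model.  Ties break toward fewer parameters, then smaller rm."""
    pooled = pd.concat([presence_values, background_values], ignore_index=True)
    candidates: list[tuple[ModelSelectionRecord, MaxentModel]] = []
    records: list[ModelSelectionRecord] = []
    for classes in class_sets:
        features = make_features(
            pooled,
            n_presence=len(presence_values),
            classes=classes,
            categorical_vars=categorical_vars,
            n_hinge=n_hinge,
        )
        for rm in rms:
            model = fit(features, presence_values, background_values, rm=rm)
            rec = aicc(model, presence_values, background_values)
            records.append(rec)
            if rec.aicc is not None:
                candidates.append((rec, model))
    if not candidates:
        raise ValueError("AICc undefined for every candidate (too few presences)")
    candidates.sort(key=lambda cm: (cm[0].aicc, cm[0].k, cm[0].rm))
    return candidates[0][1], records


@dataclasses.dataclass
class CrossValidation:
    models: list[MaxentModel]
    fold_of_presence: np.ndarray  # fold index per presence row
    test_scores: np.ndarray  # pooled held-out cloglog scores (presence order)
    train_scores: list[np.ndarray]  # per-fold training-presence scores
    background_scores: np.ndarray  # mean cloglog over folds, background rows

    def mean_map(self, stack, output: str = "cloglog"):
        """Arithmetic mean of the per-fold prediction grids."""
        from .model import predict

        grids = [predict(m, stack, output=output) for m in self.models]
        ref = grids[0]
        arr = np.mean([g.values for g in grids], axis=0)
        bad = grids[0].values == ref.nodata
        arr[bad] = ref.nodata
        return ref.copy_with(arr, kind="continuous")


def crossvalidate(
    features_classes: str,
    presence_values: pd.DataFrame,
    background_values: pd.DataFrame,
    k: int = 10,
    rm: float = 1.0,
    seed: int = 0,
    categorical_vars: tuple[str, ...] = ("landform",),
    n_hinge: int = 50,
) -> CrossValidation:
    """k-fold cross-validation: presences are partitioned at random
    (seeded), the background sample is shared across folds."""
    n = len(presence_values)
    if k > n:
        raise ValueError(f"k={k} exceeds the number of presences ({n})")
    rng = np.random.default_rng(seed)
    fold = np.repeat(np.arange(k), int(np.ceil(n / k)))[:n]
    rng.shuffle(fold)
    pooled = pd.concat([presence_values, background_values], ignore_index=True)
    features = make_features(
        pooled,
        n_presence=n,
        classes=features_classes,
        categorical_vars=categorical_vars,
        n_hinge=n_hinge,
    )
    models = []
    test_scores = np.empty(n)
    train_scores = []
    bg_scores = np.zeros(len(background_values))
    for f in range(k):
        train = presence_values[fold != f]
        test = presence_values[fold == f]
        model = fit(features, train, background_values, rm=rm)
        models.append(model)
        test_scores[fold == f] = model.cloglog(test)
        train_scores.append(model.cloglog(train))
        bg_scores += model.cloglog(background_values)
    bg_scores /= k
    return CrossValidation(models, fold, test_scores, train_scores, bg_scores)
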