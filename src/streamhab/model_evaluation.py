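"""Threshold-independent and threshold-dependent model evaluation.

Background points stand in as pseudo-absences for the confusion-matrix
metrics; AUC uses the Mann-Whitney formulation and is therefore invariant
under monotone transforms of the scores.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .maxent_engine.model import MaxentModel

__all__ = [
    "roc_auc",
    "auc_class",
    "ess_threshold",
    "confusion_counts",
    "confusion_metrics",
    "permutation_importance",
    "percent_contribution",
    "response_curve",
    "EvaluationReport",
    "evaluate",
]


def roc_auc(pos_scores: np.ndarray, neg_scores: np.ndarray) -> float:
    """P(pos > neg) + ½·P(pos = neg) via midranks."""
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both score sets must be non-empty")
    ranks = rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: len(pos)].sum()
    return float((r_pos - len(pos) * (len(pos) + 1) / 2) / (len(pos) * len(neg)))


def auc_class(auc: float) -> str:
    """Discrimination label for an AUC value."""
    if auc > 0.90:
        return "outstanding"
    if auc >= 0.80:
        return "excellent"
    if auc >= 0.70:
        return "acceptable"
    if auc >= 0.50:
        return "poor"
    return "invalid"


def ess_threshold(pos_scores: np.ndarray, neg_scores: np.ndarray) -> float:
    """Equal-sensitivity/specificity threshold.

    Candidates are midpoints of consecutive sorted unique scores; the
    lowest candidate minimizing |sensitivity − specificity| wins.
    """
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    uniq = np.unique(np.concatenate([pos, neg]))
    if len(uniq) == 1:
        return float(uniq[0])
    cands = (uniq[:-1] + uniq[1:]) / 2
    sens = np.array([(pos >= t).mean() for t in cands])
    spec = np.array([(neg < t).mean() for t in cands])
    gap = np.abs(sens - spec)
    return float(cands[np.argmin(gap)])  # argmin takes the first (lowest)


def confusion_counts(
    pos_scores: np.ndarray, neg_scores: np.ndarray, threshold: float
) -> dict[str, int]:
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    return {
        "tp": int((pos >= threshold).sum()),
        "fn": int((pos < threshold).sum()),
        "fp": int((neg >= threshold).sum()),
        "tn": int((neg < threshold).sum()),
    }


def confusion_metrics(
    pos_scores: np.ndarray, neg_scores: np.ndarray, threshold: float
) -> tuple[float, float, float]:
    """(TSS, SEDI, accuracy) of the binary prediction at ``threshold``.

    With hit rate H = sensitivity and false-alarm rate F = 1 − specificity:
    ``TSS = H − F`` and
    ``SEDI = (ln F − ln H − ln(1−F) + ln(1−H)) / (ln F + ln H + ln(1−F) + ln(1−H))``.
    H and F are clamped to [ε, 1−ε] with ε = 1/(2n) so SEDI stays finite
    at perfect or degenerate classifications.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both score sets must be non-empty")
    cm = confusion_counts(pos, neg, threshold)
    h = cm["tp"] / (cm["tp"] + cm["fn"])
    f = cm["fp"] / (cm["fp"] + cm["tn"])
    tss = h - f
    n = len(pos) + len(neg)
    eps = 1.0 / (2 * n)
    hc = min(max(h, eps), 1 - eps)
    fc = min(max(f, eps), 1 - eps)
    if hc == fc:
        sedi = 0.0
    else:
        num = np.log(fc) - np.log(hc) - np.log1p(-fc) + np.log1p(-hc)
        den = np.log(fc) + np.log(hc) + np.log1p(-fc) + np.log1p(-hc)
        sedi = float(num / den)
    accuracy = (cm["tp"] + cm["tn"]) / n
    return float(tss), sedi, float(accuracy)


def permutation_importance(
    model: MaxentModel,
    presence_values: pd.DataFrame,
    background_values: pd.DataFrame,
    seed: int = 0,
    reps: int = 10,
) -> pd.DataFrame:
    """Per-variable AUC drop when the variable is shuffled across all rows,
    averaged over ``reps`` and normalized to sum 100 (negative drops floored
    at zero)."""
    rng = np.random.default_rng(seed)
    pooled = pd.concat([presence_values, background_values], ignore_index=True)
    n_pos = len(presence_values)
    base_scores = model.cloglog(pooled)
    base_auc = roc_auc(base_scores[:n_pos], base_scores[n_pos:])
    variables = model.features.variables
    drops = {}
    for var in variables:
        acc = 0.0
        for _ in range(reps):
            shuffled = pooled.copy()
            shuffled[var] = rng.permutation(shuffled[var].to_numpy())
            s = model.cloglog(shuffled)
            acc += base_auc - roc_auc(s[:n_pos], s[n_pos:])
        drops[var] = max(acc / reps, 0.0)
    total = sum(drops.values())
    if total == 0:
        pct = {v: 0.0 for v in variables}
    else:
        pct = {v: 100.0 * d / total for v, d in drops.items()}
    return pd.DataFrame(
        {"variable": list(pct), "permutation_importance": list(pct.values())}
    )


def percent_contribution(
    model: MaxentModel, background_values: pd.DataFrame
) -> pd.DataFrame:
    """Per-variable share of Σ|λ_j|·sd_j(feature over background), as %.

    A coarse but deterministic stand-in for the path-dependent training
    accounting of the reference implementation.  Product features split
    their weight evenly between both variables.
    """
    X = model.features.transform(background_values)
    sds = X.std(axis=0)
    weights = np.abs(model.lam) * sds
    contrib: dict[str, float] = {v: 0.0 for v in model.features.variables}
    for j, f in enumerate(model.features.features):
        if f.kind == "product":
            contrib[f.var] += weights[j] / 2
            contrib[f.var2] += weights[j] / 2
        else:
            contrib[f.var] += weights[j]
    total = sum(contrib.values())
    if total == 0:
        warnings.warn("all coefficients zero; reporting uniform contributions")
        pct = {v: 100.0 / len(contrib) for v in contrib}
    else:
        pct = {v: 100.0 * c / total for v, c in contrib.items()}
    return pd.DataFrame(
        {"variable": list(pct), "percent_contribution": list(pct.values())}
    )


def response_curve(
    model: MaxentModel,
    background_values: pd.DataFrame,
    variable: str,
    n_points: int = 100,
) -> pd.DataFrame:
    """Cloglog response as ``variable`` sweeps its background range with the
    other continuous variables held at their background mean and
    categoricals at their mode."""
    base = {}
    for col in background_values.columns:
        col_vals = background_values[col]
        if col in model.features.categorical:
            base[col] = col_vals.mode().iloc[0]
        else:
            base[col] = float(col_vals.mean())
    lo = float(background_values[variable].min())
    hi = float(background_values[variable].max())
    xs = np.linspace(lo, hi, n_points)
    frame = pd.DataFrame({col: np.repeat(v, n_points) for col, v in base.items()})
    frame[variable] = xs
    return pd.DataFrame({"x": xs, "cloglog": model.cloglog(frame)})


@dataclasses.dataclass
class EvaluationReport:
    auc_train_mean: float
    auc_train_sd: float
    auc_test_mean: float
    auc_test_sd: float
    auc_class: str
    threshold_ess: float
    confusion: dict[str, int]
    tss: float
    sedi: float
    accuracy: float
    importance: pd.DataFrame

    def to_json(self, path: str | Path) -> None:
        doc = dataclasses.asdict(self)
        doc["importance"] = self.importance.to_dict(orient="records")
        Path(path).write_text(json.dumps(doc, indent=2))


def evaluate(
    cv,
    model: MaxentModel,
    presence_values: pd.DataFrame,
    background_values: pd.DataFrame,
    seed: int = 0,
) -> EvaluationReport:
    """Full report from a cross-validation and a final full-data model.

    Fold-wise train/test AUCs; the ESS threshold and confusion metrics are
    computed on the full-data model's scores of all presences against the
    background pseudo-absences.
    """
    k = len(cv.models)
    train_aucs = []
    test_aucs = []
    for f, m in enumerate(cv.models):
        bg = m.cloglog(background_values)
        train_aucs.append(roc_auc(cv.train_scores[f], bg))
        test_aucs.append(roc_auc(cv.test_scores[cv.fold_of_presence == f], bg))
    pos = model.cloglog(presence_values)
    neg = model.cloglog(background_values)
    thr = ess_threshold(pos, neg)
    tss, sedi, acc = confusion_metrics(pos, neg, thr)
    imp = permutation_importance(
        model, presence_values, background_values, seed=seed
    ).merge(percent_contribution(model, background_values), on="variable")
    test_mean = float(np.mean(test_aucs))
    return EvaluationReport(
        auc_train_mean=float(np.mean(train_aucs)),
        auc_train_sd=float(np.std(train_aucs)),
        auc_test_mean=test_mean,
        auc_test_sd=float(np.std(test_aucs)),
        auc_class=auc_class(test_mean),
        threshold_ess=thr,
        confusion=confusion_counts(pos, neg, thr),
        tss=tss,
        sedi=sedi,
        accuracy=acc,
        importance=imp,
    )
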