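"""Evaluation machinery: stratified nested CV, metrics, permutation tests.

Nested scheme: an outer k-fold whose test sets partition the cohort,
and, per fold, an inner random 90/10 train/validation split of the
non-test subjects.  All splits are stratified by sex crossed with age
discretized into (by default 15) quantile bins; strata too small for k
folds are merged with neighbouring age bins within sex.

Regression metrics: MAE, Pearson r with its two-sided p-value, and the
prediction R^2 (q^2) 1 - SS_res/SS_tot computed against the
evaluation-set mean (so cross-cohort values can be strongly negative
when a model's predictions are worse than that cohort's mean age).
Classification metrics: sensitivity, specificity, balanced accuracy
(their mean), and AUC; the operating point is chosen on validation data
as the cutoff maximizing the harmonic mean of sensitivity and
specificity, then frozen for the test set.  Significance for
classifiers comes from label-permutation tests at the prediction level.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split

logger = logging.getLogger(__name__)

__all__ = [
    "SplitPlan",
    "MetricsReport",
    "make_split_plan",
    "prediction_r2",
    "regression_metrics",
    "select_cutoff",
    "classification_metrics",
    "permutation_test",
    "select_best_model",
    "cross_dataset_evaluate",
]


# ---------------------------------------------------------------------------
# split plan


@dataclass
class SplitPlan:
    """Outer fold test sets plus per-fold inner train/validation indices."""

    outer_test: list[np.ndarray]
    inner_train: list[np.ndarray]
    inner_val: list[np.ndarray]
    strata: np.ndarray
    seed: int

    @property
    def k(self) -> int:
        return len(self.outer_test)

    def fold(self, i: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self.inner_train[i], self.inner_val[i], self.outer_test[i]

    def to_json(self, subject_ids: Sequence[str], path: Path | str) -> None:
        payload = {
            f"fold_{i}": {
                "train": [subject_ids[j] for j in self.inner_train[i]],
                "val": [subject_ids[j] for j in self.inner_val[i]],
                "test": [subject_ids[j] for j in self.outer_test[i]],
            }
            for i in range(self.k)
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def _stratum_labels(
    ages: np.ndarray, sexes: np.ndarray, n_age_bins: int, k: int
) -> np.ndarray:
    """Sex x age-quantile strata; bins merged until every stratum holds >= k.

    Quantile bins are computed on the cohort being split; boundary ties go
    to the lower bin.
    """
    n = len(ages)
    bins = min(n_age_bins, max(1, n // max(k, 1)))
    while bins >= 1:
        # quantile edges; searchsorted(side='left') sends ties to the lower bin
        qs = np.quantile(ages, np.linspace(0, 1, bins + 1)[1:-1])
        age_bin = np.searchsorted(qs, ages, side="left")
        strata = sexes.astype(int) * bins + age_bin
        counts = pd.Series(strata).value_counts()
        if counts.min() >= k:
            return strata
        if bins == 1:
            break
        bins -= 1
        logger.warning(
            "stratum smaller than k=%d; merging age bins down to %d", k, bins
        )
    return sexes.astype(int)  # age bins exhausted: stratify by sex only


def make_split_plan(
    records, k: int, n_age_bins: int = 15, seed: int = 0, val_fraction: float = 0.1
) -> SplitPlan:
    """Build the nested-CV plan for a cohort (list of records or DataFrame)."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if hasattr(records, "age"):  # DataFrame
        ages = np.asarray(records.age, dtype=float)
        sexes = np.asarray(records.sex, dtype=int)
    else:
        ages = np.array([r.age for r in records], dtype=float)
        sexes = np.array([r.sex for r in records], dtype=int)
    n = len(ages)
    if n < 2 * k:
        raise ValueError(f"cohort of {n} too small for k={k} folds")
    strata = _stratum_labels(ages, sexes, n_age_bins, k)

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    outer_test, inner_train, inner_val = [], [], []
    for i, (rest, test) in enumerate(skf.split(np.zeros(n), strata)):
        # inner stratification degrades gracefully when residual strata thin out
        for inner_strata in (strata[rest], sexes[rest], None):
            try:
                tr, va = train_test_split(
                    rest,
                    test_size=val_fraction,
                    random_state=seed + 1000 + i,
                    stratify=inner_strata,
                )
                break
            except ValueError:
                continue
        outer_test.append(np.sort(test))
        inner_train.append(np.sort(tr))
        inner_val.append(np.sort(va))
    return SplitPlan(outer_test, inner_train, inner_val, strata, seed)


# ---------------------------------------------------------------------------
# metrics


@dataclass
class MetricsReport:
    n: int
    mae: float | None = None
    pearson_r: float | None = None
    r_p_value: float | None = None
    prediction_r2: float | None = None
    sensitivity: float | None = None
    specificity: float | None = None
    balanced_accuracy: float | None = None
    auc: float | None = None
    permutation_p: float | None = None
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "extras" and v is not None}
        d.update(self.extras)
        return d


def prediction_r2(targets, estimates, baseline_mean: float | None = None) -> float:
    """Prediction R^2 (q^2): 1 - SS_res / SS_tot on held-out data.

    ``baseline_mean`` defaults to the evaluation-set mean; pass the
    training-set mean to use the alternative convention.  Unbounded
    below; raises on zero target variance.
    """
    y = np.asarray(targets, dtype=float)
    yhat = np.asarray(estimates, dtype=float)
    if y.shape != yhat.shape or y.size < 2:
        raise ValueError("targets and estimates must be equal-length, n >= 2")
    mean = float(np.mean(y)) if baseline_mean is None else float(baseline_mean)
    ss_tot = float(np.sum((y - np.mean(y)) ** 2)) if baseline_mean is None else float(
        np.sum((y - mean) ** 2)
    )
    if ss_tot <= 0:
        raise ValueError("target variance is zero; prediction R^2 undefined")
    ss_res = float(np.sum((y - yhat) ** 2))
    return 1.0 - ss_res / ss_tot


def regression_metrics(targets, estimates) -> MetricsReport:
    """MAE, Pearson r (two-sided p), prediction R^2."""
    y = np.asarray(targets, dtype=float)
    yhat = np.asarray(estimates, dtype=float)
    if y.size < 3:
        raise ValueError("need n >= 3 for a correlation p-value")
    r, p = stats.pearsonr(y, yhat)
    return MetricsReport(
        n=int(y.size),
        mae=float(np.mean(np.abs(y - yhat))),
        pearson_r=float(r),
        r_p_value=float(p),
        prediction_r2=prediction_r2(y, yhat),
    )


def _sens_spec(scores: np.ndarray, labels: np.ndarray, thr: float) -> tuple[float, float]:
    pred = scores >= thr
    pos = labels == 1
    neg = ~pos
    sens = float(np.sum(pred & pos)) / max(int(np.sum(pos)), 1)
    spec = float(np.sum(~pred & neg)) / max(int(np.sum(neg)), 1)
    return sens, spec


def select_cutoff(val_scores, val_labels) -> float:
    """Cutoff maximizing the harmonic mean of sensitivity and specificity.

    Candidates: midpoints between consecutive sorted unique scores plus
    one threshold below all scores and one above.  Chosen on validation
    data and frozen for test classification.
    """
    scores = np.asarray(val_scores, dtype=float)
    labels = np.asarray(val_labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("validation labels contain a single class")
    uniq = np.unique(scores)
    candidates = np.concatenate(
        [[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + 1.0]]
    )
    best_thr, best_h = candidates[0], -1.0
    for thr in candidates:
        sens, spec = _sens_spec(scores, labels, thr)
        h = 0.0 if sens + spec == 0 else 2 * sens * spec / (sens + spec)
        if h > best_h:
            best_h, best_thr = h, float(thr)
    return best_thr


def classification_metrics(test_scores, test_labels, threshold: float) -> MetricsReport:
    """Sensitivity/specificity at the frozen threshold; AUC threshold-free."""
    scores = np.asarray(test_scores, dtype=float)
    labels = np.asarray(test_labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("test labels contain a single class")
    sens, spec = _sens_spec(scores, labels, threshold)
    return MetricsReport(
        n=int(labels.size),
        sensitivity=sens,
        specificity=spec,
        balanced_accuracy=(sens + spec) / 2.0,
        auc=float(roc_auc_score(labels, scores)),
    )


def permutation_test(
    test_scores,
    test_labels,
    metric: Callable[[np.ndarray, np.ndarray], float],
    n_perm: int = 1000,
    seed: int = 0,
) -> float:
    """Label-permutation p-value: (1 + #{perm >= observed}) / (1 + n_perm).

    Labels are permuted while scores stay fixed; the model is not
    retrained.  ``metric(scores, labels)`` must return a finite scalar.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    scores = np.asarray(test_scores, dtype=float)
    labels = np.asarray(test_labels)
    # canonical joint order: the p-value is invariant to how the
    # (score, label) pairs were ordered on input
    order = np.lexsort((labels.astype(float), scores))
    scores, labels = scores[order], labels[order]
    observed = float(metric(scores, labels))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = metric(scores, rng.permutation(labels))
        if not np.isfinite(perm):
            raise FloatingPointError("non-finite metric under permutation")
        if perm >= observed:
            count += 1
    return (1 + count) / (1 + n_perm)


def select_best_model(cv_results: Sequence[MetricsReport], criterion: str = "pearson_r") -> int:
    """Fold index optimizing the criterion (default: highest test-set r,
    ties broken by lowest MAE; ``criterion='mae'`` selects lowest MAE)."""
    if len(cv_results) == 0:
        raise ValueError("no folds to select from")
    vals = np.array(
        [getattr(m, criterion) if getattr(m, criterion) is not None else np.nan
         for m in cv_results],
        dtype=float,
    )
    if not np.any(np.isfinite(vals)):
        raise ValueError(f"no finite {criterion!r} values across folds")
    if criterion == "mae":
        return int(np.nanargmin(vals))
    best = np.nanmax(vals)
    tied = np.flatnonzero(vals == best)
    if len(tied) > 1:
        maes = np.array([cv_results[i].mae if cv_results[i].mae is not None else np.inf
                         for i in tied])
        return int(tied[np.argmin(maes)])
    return int(tied[0])


def cross_dataset_evaluate(model, volumes: np.ndarray, targets) -> MetricsReport:
    """Evaluate a trained model on a full external cohort (no splitting).

    Flags likely range restriction (narrower target spread than typical)
    in ``extras`` so low cross-cohort correlations with small MAE can be
    read correctly.
    """
    y = np.asarray(targets, dtype=float)
    preds = model.predict(volumes)
    report = regression_metrics(y, preds)
    report.extras["target_sd"] = float(np.std(y))
    report.extras["prediction_sd"] = float(np.std(preds))
    return report
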