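"""Prediction-level confound decomposition.

How much of a model's apparent performance is really driven by measured
confounders?  Three auxiliary models are fitted to the target: (1)
confounders only, (2) model predictions only, (3) both.  From their
cross-validated coefficients of determination (R^2 for regression
targets via linear fits, D^2 = 1 - deviance/null-deviance for binary
targets via logistic fits) the explained variance splits into

    delta_predictions = fit_full - fit_conf   (unique to predictions)
    delta_confounds   = fit_full - fit_pred   (unique to confounders)
    shared            = fit_pred + fit_conf - fit_full

which always sum to ``fit_full``.  Confounder sets: sex, acquisition
site (one-hot, reference level dropped) and total brain volume for age
targets, plus age itself for diagnosis/symptom targets.  Components can
be negative under cross-validation and are reported as computed so the
additivity identity holds exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LinearRegression, LogisticRegression

__all__ = [
    "ConfoundPartition",
    "build_confound_matrix",
    "decompose",
    "decompose_single",
    "summarize_partitions",
]

_PROB_CLIP = 1e-6


@dataclass
class ConfoundPartition:
    delta_confounds: float
    delta_predictions: float
    shared: float
    full_fit: float
    target_kind: str  # "regression" | "classification"

    def __post_init__(self) -> None:
        total = self.delta_confounds + self.delta_predictions + self.shared
        if not np.isclose(total, self.full_fit, atol=1e-8):
            raise ValueError("partition components do not sum to the joint fit")


def build_confound_matrix(
    phenotypes: pd.DataFrame, include_age: bool = False
) -> np.ndarray:
    """Encode sex, one-hot site (first level dropped), total brain volume,
    and optionally age, aligned with the phenotype rows."""
    cols = [np.asarray(phenotypes.sex, dtype=float)]
    sites = np.asarray(phenotypes.site)
    levels = np.unique(sites)
    for level in levels[1:]:  # lexicographically first level is the reference
        cols.append((sites == level).astype(float))
    cols.append(np.asarray(phenotypes.total_brain_volume, dtype=float))
    if include_age:
        cols.append(np.asarray(phenotypes.age, dtype=float))
    x = np.column_stack(cols)
    if np.any(~np.isfinite(x)):
        raise ValueError("confound matrix contains missing/non-finite values")
    if np.linalg.matrix_rank(np.column_stack([np.ones(len(x)), x])) < x.shape[1] + 1:
        raise ValueError(
            "rank-deficient confound design (collinear columns among "
            "sex/site/total_brain_volume/age)"
        )
    return x


def _fit_score(
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_test: np.ndarray,
    y_test: np.ndarray,
    kind: str,
) -> float:
    """Out-of-fold R^2 (regression) or D^2 (classification) of one design."""
    if kind == "regression":
        mdl = LinearRegression().fit(x_train, y_train)
        pred = mdl.predict(x_test)
        ss_tot = float(np.sum((y_test - np.mean(y_test)) ** 2))
        if ss_tot <= 0:
            raise ValueError("zero target variance in evaluation fold")
        return 1.0 - float(np.sum((y_test - pred) ** 2)) / ss_tot
    if len(np.unique(y_train)) < 2 or len(np.unique(y_test)) < 2:
        raise ValueError("single-class target: D^2 undefined")
    mdl = LogisticRegression(penalty=None, max_iter=2000).fit(x_train, y_train)
    p = np.clip(mdl.predict_proba(x_test)[:, 1], _PROB_CLIP, 1 - _PROB_CLIP)
    dev = -2.0 * float(np.sum(y_test * np.log(p) + (1 - y_test) * np.log(1 - p)))
    p0 = np.clip(np.mean(y_test), _PROB_CLIP, 1 - _PROB_CLIP)
    null_dev = -2.0 * float(
        np.sum(y_test * np.log(p0) + (1 - y_test) * np.log(1 - p0))
    )
    return 1.0 - dev / null_dev


def decompose_single(
    target,
    predictions,
    confounders: np.ndarray,
    target_kind: str,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
) -> ConfoundPartition:
    """One train/test split's partition (fit on train, score on test)."""
    y = np.asarray(target, dtype=float)
    p = np.asarray(predictions, dtype=float).reshape(-1, 1)
    c = np.asarray(confounders, dtype=float)
    if not (len(y) == len(p) == len(c)):
        raise ValueError("target, predictions and confounders must align")
    designs = {"conf": c, "pred": p, "full": np.hstack([c, p])}
    fits = {
        k: _fit_score(d[train_idx], y[train_idx], d[test_idx], y[test_idx], target_kind)
        for k, d in designs.items()
    }
    return ConfoundPartition(
        delta_confounds=fits["full"] - fits["pred"],
        delta_predictions=fits["full"] - fits["conf"],
        shared=fits["pred"] + fits["conf"] - fits["full"],
        full_fit=fits["full"],
        target_kind=target_kind,
    )


def decompose(
    target,
    predictions,
    confounders: np.ndarray,
    target_kind: str,
    folds: Sequence[tuple[np.ndarray, np.ndarray]],
) -> list[ConfoundPartition]:
    """Per-fold partitions: the auxiliary models are fitted on each fold's
    complement and scored on its test set (the same outer test sets as the
    main pipeline).

    Requires >= 10 subjects and a full-rank confounder design.
    """
    y = np.asarray(target, dtype=float)
    if len(y) < 10:
        raise ValueError("need >= 10 subjects for a stable decomposition")
    if target_kind not in ("regression", "classification"):
        raise ValueError(f"unknown target_kind {target_kind!r}")
    return [
        decompose_single(y, predictions, confounders, target_kind, tr, te)
        for tr, te in folds
    ]


def summarize_partitions(
    partitions: Sequence[ConfoundPartition], strict: bool = True
) -> pd.DataFrame:
    """Componentwise mean +- sample sd across folds (one row per component)."""
    if len(partitions) < 2 and strict:
        raise ValueError("need >= 2 folds to summarize (or pass strict=False)")
    frame = pd.DataFrame(
        {
            "delta_confounds": [p.delta_confounds for p in partitions],
            "delta_predictions": [p.delta_predictions for p in partitions],
            "shared": [p.shared for p in partitions],
            "full_fit": [p.full_fit for p in partitions],
        }
    )
    out = pd.DataFrame(
        {
            "mean": frame.mean(),
            "sd": frame.std(ddof=1) if len(partitions) > 1 else np.nan,
        }
    )
    out.index.name = "component"
    return out
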