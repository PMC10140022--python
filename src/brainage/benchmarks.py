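"""Published benchmark metrics for the four public youth cohorts.

These are the printed performance figures reported for 3D-CNN brain-age
and diagnosis models trained on ABIDE-II, ADHD-200, BHRCS and ABCD.
They serve as worked examples for the metric definitions in
:mod:`brainage.evaluation`: recomputing balanced accuracy from the
printed sensitivity/specificity pairs, and the per-training-cohort mean
cross-dataset correlation from the printed per-evaluation-cohort
correlations, must reproduce the printed summary values.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "CLASSIFICATION_OPERATING_POINTS",
    "CROSS_DATASET_CORRELATIONS",
    "REPORTED_BALANCED_ACCURACY",
    "REPORTED_MEAN_CROSS_R",
    "balanced_accuracy_from_operating_point",
    "mean_cross_dataset_correlation",
]

# mean sensitivity/specificity over cross-validation folds (diagnosis tasks)
CLASSIFICATION_OPERATING_POINTS: dict[str, dict[str, float]] = {
    "ASD: ABIDE-II": {"specificity": 0.50, "sensitivity": 0.46},
    "ADHD: ADHD-200": {"specificity": 0.62, "sensitivity": 0.59},
}

# printed balanced accuracies for the same rows (2 d.p.)
REPORTED_BALANCED_ACCURACY: dict[str, float] = {
    "ASD: ABIDE-II": 0.48,
    "ADHD: ADHD-200": 0.60,
}

# age-model cross-dataset Pearson correlations: training cohort ->
# {evaluation cohort: r} (each best CV model evaluated on the full
# independent cohorts)
CROSS_DATASET_CORRELATIONS: dict[str, dict[str, float]] = {
    "ABIDE-II": {"ADHD-200": 0.71, "BHRCS": 0.50, "ABCD": 0.27},
    "ADHD-200": {"ABIDE-II": 0.76, "BHRCS": 0.53, "ABCD": 0.31},
    "BHRCS": {"ABIDE-II": 0.72, "ADHD-200": 0.75, "ABCD": 0.30},
    "ABCD": {"ABIDE-II": 0.65, "ADHD-200": 0.80, "BHRCS": 0.56},
}

# printed per-model mean cross-dataset correlations (2 d.p.)
REPORTED_MEAN_CROSS_R: dict[str, float] = {
    "ABCD": 0.67,
    "BHRCS": 0.59,
    "ADHD-200": 0.53,
    "ABIDE-II": 0.49,
}


def balanced_accuracy_from_operating_point(task: str) -> float:
    """Balanced accuracy = (sensitivity + specificity) / 2 for a published row."""
    op = CLASSIFICATION_OPERATING_POINTS[task]
    return (op["sensitivity"] + op["specificity"]) / 2.0


def mean_cross_dataset_correlation(training_cohort: str) -> float:
    """Mean of the published cross-dataset r's for one training cohort."""
    return float(np.mean(list(CROSS_DATASET_CORRELATIONS[training_cohort].values())))
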