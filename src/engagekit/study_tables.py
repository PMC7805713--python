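"""Published per-subject results of the engagement study this pipeline models.

The original user study (18 children, 13 typically developing and 5 with
autism spectrum disorder, interacting with two robots in a sensory-maze game)
reported per-subject metrics for the personalized classifiers and a
classifier comparison.  Those printed per-subject rows are inputs here: the
functions below recompute the study's aggregate rows (group means) from them,
which pins down the reporting conventions (unweighted arithmetic means,
4- or 2-decimal rounding) that :func:`engagekit.evaluation.summary_table`
mirrors.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

TD, ASD = "TD", "ASD"

# subject id -> (age years, gender, group)
DEMOGRAPHICS = pd.DataFrame(
    [
        (1, 10, "M", TD), (2, 4, "F", TD), (3, 5, "F", TD), (4, 11, "F", TD),
        (5, 9, "M", TD), (6, 10, "F", TD), (7, 9, "M", TD), (8, 5, "M", TD),
        (9, 5, "F", TD), (10, 5, "M", TD), (11, 5, "M", TD), (12, 5, "M", TD),
        (13, 9, "M", TD),
        (14, 7, "M", ASD), (15, 8, "M", ASD), (16, 10, "M", ASD),
        (17, 8, "M", ASD), (18, 8, "M", ASD),
    ],
    columns=["id", "age", "gender", "group"],
)

# personalized convolutional-classifier metrics per subject:
# (id, interaction length s, datapoints, train acc, train loss,
#  val acc, val loss, test acc)
INDIVIDUAL_CNN_METRICS = pd.DataFrame(
    [
        (1, 315, 9444, 0.8101, 0.5028, 0.7790, 0.6681, 0.7946),
        (2, 519, 15357, 0.6499, 0.7278, 0.6398, 0.7797, 0.6393),
        (3, 540, 16412, 0.6703, 0.8723, 0.6407, 1.0095, 0.6526),
        (4, 658, 10933, 0.8302, 0.4189, 0.8131, 0.4923, 0.8240),
        (5, 797, 22996, 0.9255, 0.1903, 0.9198, 0.2484, 0.9159),
        (6, 696, 9300, 0.9200, 0.2850, 0.8925, 0.3856, 0.9124),
        (7, 316, 9388, 0.7821, 0.5423, 0.7417, 0.7946, 0.7338),
        (8, 457, 13725, 0.7561, 0.6065, 0.7418, 0.6796, 0.7483),
        (9, 574, 10463, 0.6671, 0.8486, 0.6535, 0.9333, 0.6364),
        (10, 780, 16627, 0.9104, 0.2253, 0.8831, 0.3907, 0.8698),
        (11, 726, 12726, 0.8390, 0.3843, 0.8303, 0.4039, 0.8283),
        (12, 685, 9723, 0.8118, 0.5162, 0.7715, 0.6980, 0.7720),
        (13, 540, 12879, 0.8084, 0.4296, 0.7812, 0.5858, 0.7702),
        (14, 517, 15502, 0.8163, 0.4417, 0.7952, 0.5621, 0.7907),
        (15, 578, 14624, 0.9204, 0.2276, 0.8923, 0.3390, 0.9108),
        (16, 679, 15950, 0.6810, 0.7582, 0.6501, 0.9095, 0.6398),
        (17, 610, 16401, 0.8306, 0.3946, 0.8232, 0.4923, 0.8366),
        (18, 1058, 30508, 0.7822, 0.5467, 0.7759, 0.6323, 0.7812),
    ],
    columns=[
        "id", "interaction_s", "datapoints",
        "train_acc", "train_loss", "val_acc", "val_loss", "test_acc",
    ],
).merge(DEMOGRAPHICS[["id", "group"]], on="id")

# classifier comparison: per-subject test accuracy / weighted F1 per kind
CLASSIFIER_COMPARISON = pd.DataFrame(
    [
        (1, 0.79, 0.77, 0.77, 0.72, 0.80, 0.78, 0.77, 0.75, 0.81, 0.79),
        (2, 0.64, 0.62, 0.58, 0.55, 0.75, 0.75, 0.65, 0.64, 0.72, 0.71),
        (3, 0.65, 0.59, 0.66, 0.55, 0.67, 0.61, 0.65, 0.58, 0.67, 0.61),
        (4, 0.82, 0.79, 0.82, 0.76, 0.83, 0.81, 0.82, 0.79, 0.83, 0.81),
        (5, 0.92, 0.91, 0.89, 0.87, 0.93, 0.92, 0.90, 0.89, 0.93, 0.93),
        (6, 0.91, 0.89, 0.92, 0.90, 0.90, 0.89, 0.91, 0.89, 0.92, 0.90),
        (7, 0.73, 0.73, 0.61, 0.59, 0.80, 0.80, 0.72, 0.71, 0.80, 0.80),
        (8, 0.75, 0.74, 0.51, 0.47, 0.82, 0.82, 0.66, 0.66, 0.82, 0.81),
        (9, 0.64, 0.57, 0.63, 0.56, 0.65, 0.60, 0.63, 0.57, 0.67, 0.61),
        (10, 0.87, 0.87, 0.79, 0.77, 0.88, 0.87, 0.82, 0.82, 0.85, 0.85),
        (11, 0.77, 0.76, 0.69, 0.65, 0.78, 0.77, 0.72, 0.71, 0.76, 0.74),
        (12, 0.83, 0.78, 0.81, 0.74, 0.84, 0.81, 0.82, 0.79, 0.84, 0.80),
        (13, 0.77, 0.77, 0.73, 0.69, 0.79, 0.80, 0.77, 0.77, 0.79, 0.80),
        (14, 0.79, 0.79, 0.70, 0.69, 0.82, 0.81, 0.73, 0.73, 0.81, 0.81),
        (15, 0.91, 0.90, 0.87, 0.83, 0.92, 0.90, 0.90, 0.88, 0.92, 0.91),
        (16, 0.64, 0.62, 0.61, 0.57, 0.67, 0.65, 0.62, 0.60, 0.68, 0.66),
        (17, 0.84, 0.84, 0.70, 0.69, 0.88, 0.88, 0.76, 0.75, 0.84, 0.84),
        (18, 0.78, 0.78, 0.63, 0.60, 0.79, 0.78, 0.61, 0.58, 0.78, 0.78),
    ],
    columns=[
        "id",
        "cnn_acc", "cnn_f1", "svc_acc", "svc_f1", "rf_acc", "rf_f1",
        "dt_acc", "dt_f1", "knn_acc", "knn_f1",
    ],
).merge(DEMOGRAPHICS[["id", "group"]], on="id")


def group_age_means(decimals: int = 2) -> dict[str, float]:
    """Mean age per group, rounded to the published precision."""
    return {
        g: round(float(DEMOGRAPHICS.loc[DEMOGRAPHICS.group == g, "age"].mean()), decimals)
        for g in (TD, ASD)
    }


def group_age_stats() -> pd.DataFrame:
    """Mean and sample standard deviation of age per group (unrounded)."""
    return (
        DEMOGRAPHICS.groupby("group")["age"].agg(["mean", "std"]).loc[[TD, ASD]]
    )


def group_metric_means(decimals: int = 4) -> pd.DataFrame:
    """Group means of the per-subject classifier metrics (4-decimal rows)."""
    cols = ["interaction_s", "train_acc", "train_loss", "val_acc", "val_loss", "test_acc"]
    out = (
        INDIVIDUAL_CNN_METRICS.groupby("group")[cols]
        .mean()
        .round(decimals)
        .loc[[TD, ASD]]
    )
    out = out.rename(columns={"interaction_s": "avg_interaction_s"})
    out["avg_interaction_s"] = (
        INDIVIDUAL_CNN_METRICS.groupby("group")["interaction_s"].mean().round(1).loc[[TD, ASD]]
    )
    return out


def comparison_average_row(decimals: int = 2) -> pd.Series:
    """Mean over the 18 per-subject rows of the classifier-comparison table."""
    cols = [c for c in CLASSIFIER_COMPARISON.columns if c not in ("id", "group")]
    return CLASSIFIER_COMPARISON[cols].mean().round(decimals)


def majority_class_rate(labels: np.ndarray) -> float:
    """Share of the most frequent class — the trivial-predictor accuracy."""
    counts = np.bincount(np.asarray(labels, dtype=int))
    return float(counts.max() / counts.sum())
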