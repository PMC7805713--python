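"""Evaluation protocol: personalized, group, and combined engagement models.

Each subject gets a personalized classifier trained on their own windows;
group models pool all windows from the TD or ASD subjects (or everyone, for
the combined model).  Evaluation repeats a random 80/20 train/test split
(with 10% of the training part held out for validation) a configurable
number of times and averages the metrics.  All metrics are class-support
weighted to counter engagement-level imbalance: weighted accuracy is the
support-weighted mean of per-class recall (algebraically equal to plain
accuracy) and weighted F1 is the support-weighted mean of per-class F1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import precision_recall_fscore_support

from .dataset import WindowedDataset, concat_datasets, split
from .engagement import N_CLASSES
from .errors import ConfigError, EmptyDatasetError
from .models import CnnSpec, TrainedModel, build_cnn, predict, train, train_baseline


def weighted_metrics(y_true, y_pred) -> tuple[float, float, pd.DataFrame]:
    """(weighted accuracy, weighted F1, per-class precision/recall/F1 table)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) == 0 or len(y_true) != len(y_pred):
        raise ValueError("label vectors must be non-empty and equal length")
    labels = np.arange(N_CLASSES)
    prec, rec, f1, support = precision_recall_fscore_support(
        y_true, y_pred, labels=labels, zero_division=0
    )
    table = pd.DataFrame(
        {"class": labels, "precision": prec, "recall": rec, "f1": f1, "support": support}
    )
    w = support / support.sum()
    weighted_acc = float(np.sum(w * rec))  # == plain accuracy
    weighted_f1 = float(np.sum(w * f1))
    return weighted_acc, weighted_f1, table


@dataclass
class EvalReport:
    """Mean metrics over repeated splits for one subject/group and classifier."""

    report_id: str
    kind: str
    group: str
    n_windows: int
    train_acc: float
    train_loss: float
    val_acc: float
    val_loss: float
    test_acc: float
    test_f1: float
    per_class: pd.DataFrame
    seeds: list[int] = field(default_factory=list)
    per_rep: pd.DataFrame | None = None
    histories: list[pd.DataFrame] | None = None  # per-rep training curves (CNN)

    def row(self) -> dict:
        return {
            "id": self.report_id,
            "group": self.group,
            "classifier": self.kind,
            "n_windows": self.n_windows,
            "train_acc": self.train_acc,
            "train_loss": self.train_loss,
            "val_acc": self.val_acc,
            "val_loss": self.val_loss,
            "test_acc": self.test_acc,
            "test_f1": self.test_f1,
        }


def _audit_partition(tr, va, te, n) -> None:
    """Disjointness/exhaustiveness check on the split index sets."""
    all_idx = np.concatenate([tr, va, te])
    if len(all_idx) != n or len(np.unique(all_idx)) != n:
        raise AssertionError("train/val/test partition is not a disjoint cover")


def _fit_one(
    kind: str,
    train_ds: WindowedDataset,
    val_ds: WindowedDataset,
    seed: int,
    spec: CnnSpec,
) -> TrainedModel:
    if kind == "CNN":
        net = build_cnn(spec, seed=seed)
        return train(net, train_ds, val_ds, seed=seed, spec=spec)
    return train_baseline(kind, train_ds, seed=seed)


def _evaluate_once(
    dataset: WindowedDataset,
    kind: str,
    seed: int,
    spec: CnnSpec,
    test_fraction: float,
) -> dict:
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(dataset))
    n = len(dataset)
    n_test = int(np.floor(n * test_fraction))
    n_val = int(np.floor((n - n_test) * 0.1))
    te, va, tr = order[:n_test], order[n_test : n_test + n_val], order[n_test + n_val :]
    _audit_partition(tr, va, te, n)
    train_ds, val_ds, test_ds = (dataset.subset(i) for i in (tr, va, te))

    fitted = _fit_one(kind, train_ds, val_ds, seed, spec)
    out = {"seed": seed}
    tr_acc, _, _ = weighted_metrics(train_ds.labels, predict(fitted, train_ds))
    out["train_acc"] = tr_acc
    if len(val_ds):
        va_acc, _, _ = weighted_metrics(val_ds.labels, predict(fitted, val_ds))
    else:
        va_acc = np.nan
    out["val_acc"] = va_acc
    if kind == "CNN" and fitted.history is not None and len(fitted.history):
        last = fitted.history.iloc[-1]
        out["train_loss"] = float(last["train_loss"])
        out["val_loss"] = float(last["val_loss"])
    else:
        out["train_loss"] = np.nan
        out["val_loss"] = np.nan
    y_pred = predict(fitted, test_ds)
    te_acc, te_f1, per_class = weighted_metrics(test_ds.labels, y_pred)
    out["test_acc"] = te_acc
    out["test_f1"] = te_f1
    out["_per_class"] = per_class
    out["_history"] = fitted.history
    return out


def evaluate_subject(
    dataset: WindowedDataset,
    kinds: tuple[str, ...] = ("CNN",),
    reps: int = 10,
    seed: int = 0,
    spec: CnnSpec | None = None,
    test_fraction: float = 0.2,
) -> dict[str, EvalReport]:
    """Repeated random-split evaluation of one subject's dataset.

    Runs ``reps`` independent 80/20 splits (fresh derived seed per
    repetition, logged in the report) for every classifier kind and averages
    the metrics.
    """
    if len(dataset) < 10:
        raise EmptyDatasetError(
            f"{dataset.subject_id}: {len(dataset)} windows are too few to split"
        )
    spec = spec or CnnSpec()
    master = np.random.default_rng(seed)
    rep_seeds = [int(s) for s in master.integers(0, 2**31 - 1, size=reps)]
    reports = {}
    for kind in kinds:
        rows = [
            _evaluate_once(dataset, kind, s, spec, test_fraction) for s in rep_seeds
        ]
        per_rep = pd.DataFrame(
            [{k: v for k, v in r.items() if not k.startswith("_")} for r in rows]
        )
        mean_per_class = (
            pd.concat([r["_per_class"] for r in rows]).groupby("class").mean().reset_index()
        )
        reports[kind] = EvalReport(
            report_id=dataset.subject_id,
            kind=kind,
            group=dataset.group,
            n_windows=len(dataset),
            train_acc=float(per_rep["train_acc"].mean()),
            train_loss=float(per_rep["train_loss"].mean()),
            val_acc=float(per_rep["val_acc"].mean()),
            val_loss=float(per_rep["val_loss"].mean()),
            test_acc=float(per_rep["test_acc"].mean()),
            test_f1=float(per_rep["test_f1"].mean()),
            per_class=mean_per_class,
            seeds=rep_seeds,
            per_rep=per_rep,
            histories=[r["_history"] for r in rows if r["_history"] is not None] or None,
        )
    return reports


def evaluate_group(
    datasets: list[WindowedDataset],
    grouping: str,
    kinds: tuple[str, ...] = ("CNN",),
    reps: int = 10,
    seed: int = 0,
    spec: CnnSpec | None = None,
    test_fraction: float = 0.2,
) -> dict[str, EvalReport]:
    """Pool subjects' windows into one dataset, then evaluate as a group model.

    ``grouping`` is "TD", "ASD" or "combined"; it selects which datasets to
    pool (by their group tag; "combined" pools everything).
    """
    if grouping in ("TD", "ASD"):
        members = [d for d in datasets if d.group == grouping]
    elif grouping == "combined":
        members = list(datasets)
    else:
        raise ConfigError(f"unknown grouping: {grouping!r}")
    if not members:
        raise EmptyDatasetError(f"no datasets in group {grouping!r}")
    pooled = concat_datasets(members, subject_id=grouping, group=grouping)
    return evaluate_subject(
        pooled, kinds=kinds, reps=reps, seed=seed, spec=spec, test_fraction=test_fraction
    )


def summary_table(
    reports: list[EvalReport],
    decimals: int = 4,
    group_means: bool = True,
) -> pd.DataFrame:
    """Per-row metrics plus unweighted group-mean rows.

    ``decimals`` controls the export rounding convention (4 for the detailed
    per-subject table, 2 for the compact classifier-comparison table).
    """
    if not reports:
        raise ValueError("no reports")
    rows = pd.DataFrame([r.row() for r in reports])
    metric_cols = [c for c in rows.columns if c not in ("id", "group", "classifier", "n_windows")]
    parts = [rows]
    if group_means:
        mean_rows = []
        for kind in rows["classifier"].unique():
            sub = rows[rows["classifier"] == kind]
            mean_rows.append(
                {"id": "Average", "group": "", "classifier": kind, "n_windows": sub["n_windows"].sum(),
                 **{c: sub[c].mean() for c in metric_cols}}
            )
            for g in ("TD", "ASD"):
                gsub = sub[sub["group"] == g]
                if len(gsub):
                    mean_rows.append(
                        {"id": g, "group": g, "classifier": kind, "n_windows": gsub["n_windows"].sum(),
                         **{c: gsub[c].mean() for c in metric_cols}}
                    )
        parts.append(pd.DataFrame(mean_rows))
    out = pd.concat(parts, ignore_index=True)
    out[metric_cols] = out[metric_cols].round(decimals)
    return out
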