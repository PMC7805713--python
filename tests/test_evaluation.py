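"""Weighted metrics and the repeated-split evaluation protocol."""

import numpy as np
import pandas as pd
import pytest

from engagekit.dataset import WindowedDataset
from engagekit.engagement import N_CLASSES
from engagekit.errors import ConfigError, EmptyDatasetError
from engagekit.evaluation import (
    EvalReport,
    evaluate_group,
    evaluate_subject,
    summary_table,
    weighted_metrics,
)
from engagekit.study_tables import (
    INDIVIDUAL_CNN_METRICS,
    group_metric_means,
)


def reference_weighted_metrics(y_true, y_pred):
    """Independent confusion-matrix implementation (loops, no sklearn)."""
    cm = np.zeros((N_CLASSES, N_CLASSES), dtype=int)
    for t, p in zip(y_true, y_pred):
        cm[t, p] += 1
    support = cm.sum(axis=1)
    acc = 0.0
    f1w = 0.0
    n = support.sum()
    for k in range(N_CLASSES):
        tp = cm[k, k]
        fp = cm[:, k].sum() - tp
        fn = support[k] - tp
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        acc += (support[k] / n) * rec
        f1w += (support[k] / n) * f1
    return acc, f1w


class TestWeightedMetrics:
    def test_perfect_prediction(self):
        y = np.array([0, 1, 2, 3, 4, 5, 6] * 3)
        acc, f1, table = weighted_metrics(y, y)
        assert acc == pytest.approx(1.0, abs=1e-12)
        assert f1 == pytest.approx(1.0, abs=1e-12)
        assert (table["recall"][table["support"] > 0] == 1.0).all()

    def test_constant_predictor_on_balanced_two_classes(self):
        y_true = np.array([0] * 50 + [1] * 50)
        y_pred = np.zeros(100, dtype=int)
        acc, f1, _ = weighted_metrics(y_true, y_pred)
        assert acc == pytest.approx(0.5)
        assert f1 == pytest.approx(1 / 3)  # per-class F1 (2/3, 0), weights (.5, .5)

    def test_agrees_with_confusion_matrix_reference_exactly(self):
        rng = np.random.default_rng(123)
        for _ in range(1000):
            n = rng.integers(5, 60)
            y_true = rng.integers(0, 7, n)
            y_pred = rng.integers(0, 7, n)
            acc, f1, _ = weighted_metrics(y_true, y_pred)
            ref_acc, ref_f1 = reference_weighted_metrics(y_true, y_pred)
            assert acc == pytest.approx(ref_acc, abs=1e-12)
            assert f1 == pytest.approx(ref_f1, abs=1e-12)
            # weighted accuracy is algebraically plain accuracy
            assert acc == pytest.approx(float(np.mean(y_true == y_pred)), abs=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            weighted_metrics([], [])


def _subject(n=200, seed=0, sid="S01", group="TD", informative=True):
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 3, n)
    shift = (10.0 * y)[:, None, None] if informative else 0.0
    X = rng.normal(0, 0.5, size=(n, 5, 71)) + shift
    return WindowedDataset(X, y, sid, group)


class TestEvaluateSubject:
    def test_identical_seeds_identical_reports(self):
        ds = _subject()
        a = evaluate_subject(ds, kinds=("DT",), reps=3, seed=7)["DT"]
        b = evaluate_subject(ds, kinds=("DT",), reps=3, seed=7)["DT"]
        assert a.seeds == b.seeds
        pd.testing.assert_frame_equal(a.per_rep, b.per_rep)

    def test_partitions_audited_every_repetition(self):
        # the audit raises if the split is not a disjoint cover; 10 reps run clean
        ds = _subject()
        rep = evaluate_subject(ds, kinds=("DT",), reps=10, seed=1)["DT"]
        assert len(rep.per_rep) == 10
        assert len(set(rep.seeds)) == 10

    def test_learned_metrics_on_separable_subject(self):
        rep = evaluate_subject(_subject(400), kinds=("RF",), reps=2, seed=0)["RF"]
        assert rep.test_acc >= 0.9 and rep.test_f1 >= 0.9
        assert 0 <= rep.val_acc <= 1

    def test_too_few_windows_rejected(self):
        with pytest.raises(EmptyDatasetError):
            evaluate_subject(_subject(5), kinds=("DT",))


class TestEvaluateGroup:
    def test_single_subject_group_equals_subject_evaluation(self):
        ds = _subject(sid="S01", group="TD")
        solo = evaluate_subject(ds, kinds=("DT",), reps=2, seed=3)["DT"]
        grp = evaluate_group([ds], "TD", kinds=("DT",), reps=2, seed=3)["DT"]
        assert grp.test_acc == pytest.approx(solo.test_acc)
        assert grp.n_windows == solo.n_windows

    def test_conflicting_subjects_hurt_the_group_model(self):
        a = _subject(300, seed=1, sid="A", group="TD")
        # subject B maps the same features to reversed labels
        b = WindowedDataset(a.sequences.copy(), 2 - a.labels, "B", "TD")
        solo_a = evaluate_subject(a, kinds=("DT",), reps=2, seed=0)["DT"].test_acc
        solo_b = evaluate_subject(b, kinds=("DT",), reps=2, seed=0)["DT"].test_acc
        grp = evaluate_group([a, b], "TD", kinds=("DT",), reps=2, seed=0)["DT"].test_acc
        assert grp < min(solo_a, solo_b)

    def test_unknown_grouping_rejected(self):
        with pytest.raises(ConfigError):
            evaluate_group([_subject()], "XX")

    def test_empty_group_rejected(self):
        with pytest.raises(EmptyDatasetError):
            evaluate_group([_subject(group="TD")], "ASD")


def _report(sid, group, kind, **metrics):
    base = dict(train_acc=0.0, train_loss=0.0, val_acc=0.0, val_loss=0.0,
                test_acc=0.0, test_f1=0.0)
    base.update(metrics)
    return EvalReport(report_id=sid, kind=kind, group=group, n_windows=10,
                      per_class=pd.DataFrame(), **base)


class TestSummaryTable:
    def test_mean_of_two_rows(self):
        reports = [_report("a", "TD", "DT", test_acc=0.8),
                   _report("b", "TD", "DT", test_acc=0.6)]
        table = summary_table(reports)
        avg = table[table["id"] == "Average"].iloc[0]
        assert avg["test_acc"] == pytest.approx(0.7)

    def test_group_means_reproducible_from_rows(self):
        rng = np.random.default_rng(0)
        reports = [
            _report(f"s{i}", "TD" if i < 4 else "ASD", "RF",
                    test_acc=float(rng.uniform(0.5, 1.0)))
            for i in range(6)
        ]
        table = summary_table(reports, decimals=6)
        td_rows = table[(table["group"] == "TD") & (table["id"].str.startswith("s"))]
        td_mean = table[table["id"] == "TD"].iloc[0]["test_acc"]
        assert td_mean == pytest.approx(td_rows["test_acc"].mean(), abs=1e-6)

    def test_published_per_subject_rows_reproduce_group_means(self):
        # the study's detailed per-subject table, averaged per group at
        # 4 decimals, must reproduce its printed summary rows
        means = group_metric_means(decimals=4)
        assert means.loc["TD", "train_acc"] == 0.7985
        assert means.loc["ASD", "test_acc"] == 0.7918
        assert means.loc["TD", "test_acc"] == 0.7767
        # and the summary_table convention matches the same arithmetic
        reports = [
            _report(str(r.id), r.group, "CNN", train_acc=r.train_acc, test_acc=r.test_acc)
            for r in INDIVIDUAL_CNN_METRICS.itertuples()
        ]
        table = summary_table(reports, decimals=4)
        assert table[table["id"] == "TD"].iloc[0]["train_acc"] == 0.7985
        assert table[table["id"] == "ASD"].iloc[0]["test_acc"] == 0.7918
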