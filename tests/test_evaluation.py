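import numpy as np
import pytest

from cfsa import ConfusionCounts, FitnessSpec, compute_metrics, evaluate_mask, roc_auc


def _pair_statistic_auc(scores, labels):
    """Independent oracle: P(score+ > score-) + 0.5 P(tie), by enumeration."""
    pos = scores[labels]
    neg = scores[~labels]
    wins = ties = 0
    for p in pos:
        for n in neg:
            wins += p > n
            ties += p == n
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def _counting_metrics(y_true, y_pred):
    """Instance-by-instance counting oracle for the binary metrics."""
    tp = sum(1 for t, p in zip(y_true, y_pred) if t and p)
    fp = sum(1 for t, p in zip(y_true, y_pred) if not t and p)
    fn = sum(1 for t, p in zip(y_true, y_pred) if t and not p)
    tn = sum(1 for t, p in zip(y_true, y_pred) if not t and not p)
    acc = (tp + tn) / len(y_true)
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    return ConfusionCounts(tp, fp, fn, tn), acc, prec, rec, f1


def test_perfect_classifier_scores_one():
    m = compute_metrics(ConfusionCounts(tp=1, fp=0, fn=0, tn=1))
    assert all(v == 1.0 for v in m.values())


def test_worked_confusion_case():
    m = compute_metrics(ConfusionCounts(tp=50, fp=10, fn=5, tn=35))
    assert m["accuracy"] == pytest.approx(0.85)
    assert m["precision"] == pytest.approx(50 / 60)
    assert m["recall"] == pytest.approx(50 / 55)
    assert m["f1"] == pytest.approx(2 * (50 / 60) * (50 / 55) / (50 / 60 + 50 / 55))


def test_zero_denominator_convention_warns():
    with pytest.warns(UserWarning, match="precision"):
        m = compute_metrics(ConfusionCounts(tp=0, fp=0, fn=3, tn=7))
    assert m["precision"] == 0.0 and m["f1"] == 0.0


def test_metrics_match_counting_oracle_on_random_instances():
    rng = np.random.default_rng(0)
    for _ in range(100):
        n = rng.integers(2, 40)
        y_true = rng.random(n) < 0.5
        y_pred = rng.random(n) < 0.5
        counts, acc, prec, rec, f1 = _counting_metrics(y_true, y_pred)
        got = compute_metrics(counts)
        assert got["accuracy"] == pytest.approx(acc)
        assert got["precision"] == pytest.approx(prec)
        assert got["recall"] == pytest.approx(rec)
        assert got["f1"] == pytest.approx(f1)


def test_macro_averaging_matches_sklearn():
    from sklearn.metrics import precision_recall_fscore_support

    rng = np.random.default_rng(1)
    for _ in range(20):
        y_true = rng.integers(0, 3, 60)
        y_pred = rng.integers(0, 3, 60)
        table = np.zeros((3, 3), dtype=int)
        for t, p in zip(y_true, y_pred):
            table[t, p] += 1
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # zero-denominator classes may warn
            got = compute_metrics(table, averaging="macro")
        p, r, f, _ = precision_recall_fscore_support(
            y_true, y_pred, average="macro", zero_division=0
        )
        assert got["precision"] == pytest.approx(p)
        assert got["recall"] == pytest.approx(r)
        assert got["f1"] == pytest.approx(f)
        assert got["accuracy"] == pytest.approx(np.mean(y_true == y_pred))


@pytest.mark.parametrize(
    "scores, labels, expected",
    [
        ([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0], 1.0),
        ([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0], 0.5),
        ([0.9, 0.8, 0.3], [1, 0, 1], 0.5),  # one winning pair, one losing
    ],
)
def test_roc_auc_examples(scores, labels, expected):
    points, auc = roc_auc(np.array(scores), np.array(labels, bool))
    assert auc == pytest.approx(expected)
    assert points[0] == (0.0, 0.0) and points[-1] == (1.0, 1.0)


def test_roc_points_monotone():
    rng = np.random.default_rng(3)
    points, _ = roc_auc(rng.random(50), rng.random(50) < 0.4)
    fpr, tpr = np.array(points).T
    assert (np.diff(fpr) >= 0).all() and (np.diff(tpr) >= 0).all()


def test_trapezoid_equals_pair_statistic():
    rng = np.random.default_rng(2)
    for _ in range(30):
        n = rng.integers(4, 60)
        labels = rng.random(n) < 0.5
        if labels.all() or not labels.any():
            continue
        scores = np.round(rng.random(n), 2)  # coarse grid forces ties
        _, auc = roc_auc(scores, labels)
        assert auc == pytest.approx(_pair_statistic_auc(scores, labels), abs=1e-12)


def test_relabeling_flips_auc():
    rng = np.random.default_rng(4)
    scores = rng.random(40)
    labels = rng.random(40) < 0.5
    _, auc = roc_auc(scores, labels)
    _, flipped = roc_auc(-scores, labels)
    assert flipped == pytest.approx(1 - auc, abs=1e-12)


def test_roc_single_class_errors():
    with pytest.raises(ValueError):
        roc_auc(np.array([0.1, 0.9]), np.array([True, True]))


def test_evaluate_mask_separable(separable_dataset, fast_spec):
    report = evaluate_mask(separable_dataset, np.array([True, False, False]), fast_spec)
    assert report.accuracy == pytest.approx(1.0)
    assert report.f1 == pytest.approx(1.0)
    assert report.auc == pytest.approx(1.0)
    assert report.averaging == "binary"
    assert isinstance(report.counts, ConfusionCounts)
    assert report.counts.total == separable_dataset.n_samples


def test_evaluate_mask_multiclass_macro():
    from cfsa import Dataset

    rng = np.random.default_rng(6)
    n = 90
    y = np.repeat([0, 1, 2], n // 3)
    X = rng.standard_normal((n, 3))
    X[:, 0] += 3 * y
    ds = Dataset(X, ["a", "b", "c"], ["numeric"] * 3, y, np.zeros((n, 3), bool),
                 provenance="synthetic")
    report = evaluate_mask(ds, np.array([True, False, False]),
                           FitnessSpec(cv_folds=3, cv_seed=0))
    assert report.averaging == "macro"
    assert report.accuracy > 0.8
    assert np.asarray(report.counts).shape == (3, 3)


def test_report_writers(tmp_path, separable_dataset, fast_spec):
    report = evaluate_mask(separable_dataset, np.array([True, True, False]), fast_spec)
    report.write_json(tmp_path / "m.json")
    report.write_csv(tmp_path / "m.csv")
    report.write_roc_csv(tmp_path / "roc.csv")
    assert (tmp_path / "m.json").stat().st_size > 0
    assert (tmp_path / "roc.csv").read_text().startswith("fpr,tpr")
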