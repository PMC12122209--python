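"""Metric suite, stratified fold construction, cross-validation orchestration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dysfuse import (
    CVConfig,
    Label,
    compute_metrics,
    cross_validate,
    stratified_folds,
)
from dysfuse.evaluation import MetricSet, auc_mann_whitney
from dysfuse.synthetic import SyntheticConfig, generate


def labels_of(n_p, n_a):
    return [Label.P] * n_p + [Label.A] * n_a


def metrics_from_confusion(tp, fn, tn, fp) -> MetricSet:
    y_true = labels_of(tp + fn, tn + fp)
    y_pred = (
        [Label.P] * tp + [Label.A] * fn + [Label.A] * tn + [Label.P] * fp
    )
    return compute_metrics(y_true, y_pred)


def brute_force_auc(y, s):
    """All-pairs comparison count with tie half-credit."""
    pos = [x for x, t in zip(s, y) if t == 1]
    neg = [x for x, t in zip(s, y) if t == 0]
    if not pos or not neg:
        return None
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestComputeMetrics:
    def test_hand_computed_confusion(self):
        # TP=170, FN=10, TN=45, FP=12
        m = metrics_from_confusion(170, 10, 45, 12)
        assert m.confusion == (170, 12, 45, 10)
        assert m.SEN == pytest.approx(0.9444, abs=5e-5)
        assert m.SPE == pytest.approx(0.7895, abs=5e-5)
        assert m.BAC == pytest.approx(0.8670, abs=5e-5)
        assert m.PRE == pytest.approx(0.9341, abs=5e-5)

    def test_perfect_predictions(self):
        y = labels_of(3, 2)
        s = [0.9, 0.8, 0.7, 0.2, 0.1]
        m = compute_metrics(y, y, s)
        assert (m.SEN, m.SPE, m.BAC, m.PRE, m.AUC) == (1, 1, 1, 1, 1)

    def test_all_P_predictor_degenerates(self):
        y = labels_of(3, 2)
        m = compute_metrics(y, [Label.P] * 5)
        assert (m.SEN, m.SPE, m.BAC) == (1.0, 0.0, 0.5)

    def test_undefined_ratios_flagged_not_nan(self):
        # no predicted positives -> PRE undefined; single-class truth -> AUC None
        y = labels_of(2, 2)
        m = compute_metrics(y, [Label.A] * 4, [0.1, 0.2, 0.3, 0.4])
        assert m.PRE is None
        m2 = compute_metrics(labels_of(3, 0), [Label.P] * 3, [0.5, 0.6, 0.7])
        assert m2.AUC is None and m2.SPE is None and m2.BAC is None

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            compute_metrics(labels_of(1, 1), [Label.P])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.integers(0, 50), st.integers(0, 50), st.integers(0, 50),
           st.integers(0, 50))
    def test_bac_identity_holds_exactly(self, tp, fn, tn, fp):
        m = metrics_from_confusion(tp, fn, tn, fp)
        if m.SEN is not None and m.SPE is not None:
            assert m.BAC == (m.SEN + m.SPE) / 2  # exact, no tolerance

    def test_auc_equals_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            n = rng.integers(2, 51)
            y = rng.integers(0, 2, n)
            # duplicate-heavy scores exercise the tie handling
            s = rng.choice([0.1, 0.25, 0.5, 0.5, 0.75, 0.9], size=n)
            expected = brute_force_auc(list(y), list(s))
            got = auc_mann_whitney(y, s)
            if expected is None:
                assert got is None
            else:
                assert got == pytest.approx(expected, abs=1e-12)

    def test_auc_matches_sklearn_reference(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(5)
        y = np.array([1] * 30 + [0] * 10)
        s = rng.random(40)
        assert auc_mann_whitney(y, s) == pytest.approx(roc_auc_score(y, s))


class TestStratifiedFolds:
    def test_paper_counts_split_exactly(self):
        # 180 P / 57 A at k=5: every fold 36 P and 11 or 12 A
        folds = stratified_folds(labels_of(180, 57), 5, seed=0)
        y = np.array([1] * 180 + [0] * 57)
        for f in range(5):
            te = folds.test_indices(f)
            assert (y[te] == 1).sum() == 36
            assert (y[te] == 0).sum() in (11, 12)

    def test_each_sample_tests_exactly_once(self):
        folds = stratified_folds(labels_of(180, 57), 5, seed=3)
        seen = np.concatenate([folds.test_indices(f) for f in range(5)])
        assert sorted(seen) == list(range(237))

    def test_exact_division_balanced(self):
        folds = stratified_folds(labels_of(10, 10), 5, seed=0)
        y = np.array([1] * 10 + [0] * 10)
        for f in range(5):
            te = folds.test_indices(f)
            assert (y[te] == 1).sum() == 2 and (y[te] == 0).sum() == 2

    def test_deterministic_given_seed(self):
        a = stratified_folds(labels_of(30, 12), 4, seed=7)
        b = stratified_folds(labels_of(30, 12), 4, seed=7)
        np.testing.assert_array_equal(a.fold_of_sample, b.fold_of_sample)
        c = stratified_folds(labels_of(30, 12), 4, seed=8)
        assert not np.array_equal(a.fold_of_sample, c.fold_of_sample)

    def test_class_smaller_than_k_rejected(self):
        with pytest.raises(ValueError, match="A has 3"):
            stratified_folds(labels_of(20, 3), 5, seed=0)
        with pytest.raises(ValueError, match="k must be"):
            stratified_folds(labels_of(5, 5), 1, seed=0)


@pytest.fixture(scope="module")
def small_run():
    ds = generate(SyntheticConfig(n_P=60, n_A=20, seed=1))
    report = cross_validate(ds.manifest, ds.view1, ds.view2, CVConfig(seed=1))
    return ds, report


class TestCrossValidate:
    def test_report_shape(self, small_run):
        _, report = small_run
        for model in ("CP", "CA", "fusion"):
            assert len(report.per_fold[model]) == 5
            for metric in ("BAC", "SEN", "SPE", "PRE", "AUC"):
                mean, sd = report.aggregate[model][metric]
                assert mean is None or 0 <= mean <= 1

    def test_aggregate_recomputable_from_per_fold(self, small_run):
        _, report = small_run
        for model in ("CP", "CA", "fusion"):
            vals = [ms.BAC for ms in report.per_fold[model]]
            mean, sd = report.aggregate[model]["BAC"]
            assert mean == pytest.approx(float(np.mean(vals)), abs=0)
            assert sd == pytest.approx(float(np.std(vals, ddof=1)), abs=0)

    def test_decisions_cover_every_sample_once(self, small_run):
        ds, report = small_run
        ids = [d.sample_id for fold in report.decisions for d in fold]
        assert sorted(ids) == sorted(ds.manifest.sample_ids)

    def test_deterministic_given_seed(self):
        ds = generate(SyntheticConfig(n_P=40, n_A=16, seed=2))
        r1 = cross_validate(ds.manifest, ds.view1, ds.view2, CVConfig(seed=4))
        r2 = cross_validate(ds.manifest, ds.view1, ds.view2, CVConfig(seed=4))
        for model in ("CP", "CA", "fusion"):
            for a, b in zip(r1.per_fold[model], r2.per_fold[model]):
                assert a == b

    def test_no_leakage_from_test_rows(self):
        """Held-out scores are identical whether or not the test rows were
        present anywhere near the fitted components: fitting on the training
        indices of the full dataset equals fitting on a dataset from which
        the test rows were physically removed."""
        from dysfuse import classifier as vc
        from dysfuse.data_io import FeatureView

        ds = generate(SyntheticConfig(n_P=40, n_A=16, seed=5))
        labels = ds.manifest.labels
        folds = stratified_folds(labels, 4, seed=0)
        tr, te = folds.train_indices(0), folds.test_indices(0)
        view = ds.view1
        ids = np.array(view.sample_ids, dtype=object)
        la = np.array(labels, dtype=object)

        train_only = FeatureView("v", tuple(ids[tr]), view.matrix[tr])
        clf = vc.train(train_only, list(la[tr]), seed=0)
        test_view = FeatureView("v", tuple(ids[te]), view.matrix[te])
        out_a = vc.predict(clf, test_view)

        # same training rows, but the classifier never saw the file containing
        # the test rows at all (fresh arrays)
        clf_b = vc.train(
            FeatureView("v", tuple(ids[tr]), view.matrix[tr].copy()),
            list(la[tr]),
            seed=0,
        )
        out_b = vc.predict(clf_b, test_view)
        np.testing.assert_array_equal(out_a.score_P, out_b.score_P)

    def test_misaligned_views_rejected(self):
        ds = generate(SyntheticConfig(n_P=10, n_A=10, seed=0))
        ds2 = generate(SyntheticConfig(n_P=10, n_A=10, seed=1))
        from dysfuse.data_io import FeatureView

        reordered = FeatureView(
            "v", tuple(reversed(ds.view2.sample_ids)), ds.view2.matrix[::-1]
        )
        with pytest.raises(ValueError, match="aligned"):
            cross_validate(ds.manifest, ds.view1, reordered, CVConfig(seed=0))

    def test_table_lists_all_models(self, small_run):
        _, report = small_run
        text = report.table()
        for model in ("CP", "CA", "fusion"):
            assert model in text

    def test_csv_export_round_trip(self, small_run, tmp_path):
        import csv as csvmod

        _, report = small_run
        p = tmp_path / "report.csv"
        report.write_csv(p)
        with open(p) as fh:
            rows = list(csvmod.reader(fh))
        assert rows[0][:2] == ["model", "fold"]
        fold_rows = [r for r in rows[1:] if r[1].isdigit()]
        assert len(fold_rows) == 15  # 3 models x 5 folds
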