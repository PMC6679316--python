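"""Splitting, classifier tuning, evaluation metrics and the benchmark grid."""

import numpy as np
import pytest

import grainspec as gs
from grainspec.classify import default_spec
from tests.conftest import make_table


class TestSplit:
    def test_exact_300_100_at_study_scale(self, table_400):
        cal, pred = gs.split_calibration_prediction(table_400, (3, 1), seed=0)
        assert cal.n_samples == 300
        assert pred.n_samples == 100

    def test_smallest_case(self):
        table = make_table(np.random.default_rng(0).normal(size=(4, 5)),
                           labels=np.array([1, 2, 3, 4]))
        cal, pred = gs.split_calibration_prediction(table, (3, 1), seed=0)
        assert cal.n_samples == 3 and pred.n_samples == 1

    def test_deterministic_disjoint_exhaustive(self, table_400):
        c1, p1 = gs.split_calibration_prediction(table_400, (3, 1), seed=42)
        c2, p2 = gs.split_calibration_prediction(table_400, (3, 1), seed=42)
        assert np.array_equal(c1.ids, c2.ids)
        assert np.array_equal(p1.ids, p2.ids)
        assert len(set(c1.ids) & set(p1.ids)) == 0
        assert set(c1.ids) | set(p1.ids) == set(table_400.ids)
        # different seed -> different partition
        c3, _ = gs.split_calibration_prediction(table_400, (3, 1), seed=43)
        assert not np.array_equal(c1.ids, c3.ids)

    def test_per_class_counts_sum_to_totals(self, table_400):
        cal, pred = gs.split_calibration_prediction(table_400, (3, 1), seed=1)
        for c in (1, 2, 3, 4):
            n_c = (cal.labels == c).sum() + (pred.labels == c).sum()
            assert n_c == 100

    def test_empty_side_rejected(self):
        table = make_table(np.ones((1, 4)), labels=np.array([1]))
        with pytest.raises(ValueError, match="empty"):
            gs.split_calibration_prediction(table, (3, 1), seed=0)


def _two_cluster_table(n_per=30, seed=0):
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(-5, 0.2, size=(n_per, 4)),
                   rng.normal(+5, 0.2, size=(n_per, 4))])
    y = np.repeat([1, 2], n_per)
    return make_table(X, labels=y)


class TestTuneTrain:
    def test_separated_clusters_reach_perfect_cv_everywhere(self):
        table = _two_cluster_table()
        for family in ("DT", "KNN", "SVM"):
            model = gs.tune_train(table, default_spec(family, rng_seed=0))
            assert model.cv_accuracy == 1.0

    def test_svm_tie_break_prefers_smallest_c(self):
        """When every (c, g) ties at 100% CV accuracy the smallest penalty
        wins (simplest-model rule)."""
        model = gs.tune_train(_two_cluster_table(),
                              default_spec("SVM", rng_seed=0))
        assert model.best_params["c"] == 2.0 ** -5

    def test_dt_tie_break_prefers_largest_minleaf(self):
        # 200 samples so even a minleaf-64 tree can split each CV fold
        model = gs.tune_train(_two_cluster_table(n_per=100),
                              default_spec("DT", rng_seed=0))
        assert model.best_params["minleaf"] == 64

    def test_knn_k1_in_sample_is_perfect(self):
        table = _two_cluster_table(n_per=10)
        spec = gs.ModelSpec("KNN", grid=({"k": 1},), cv_folds=2, rng_seed=0)
        model = gs.tune_train(table, spec)
        report = gs.evaluate(model, table, "calibration")
        assert report.overall == 100.0

    def test_svm_beats_dt_on_msc_nca_bands(self, table_400):
        """On the default table reduced to NCA bands after MSC, the tuned SVM
        reaches at least the tuned tree's CV accuracy."""
        cal, _ = gs.split_calibration_prediction(
            gs.trim_bands(table_400, 931.8, 1653.8), (3, 1), seed=0)
        calp = gs.msc_apply(cal, gs.msc_fit(cal))
        sel = gs.nca_select(calp, gs.NcaParams(rng_seed=0))
        reduced = calp.take_bands(sel.indices)
        svm = gs.tune_train(reduced, default_spec("SVM", rng_seed=0))
        dt = gs.tune_train(reduced, default_spec("DT", rng_seed=0))
        assert svm.cv_accuracy >= dt.cv_accuracy

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            gs.ModelSpec("KNN", grid=())


class _ConstModel:
    def __init__(self, labels):
        self._labels = np.asarray(labels)

    def predict(self, X):
        return self._labels[: len(X)]


def _report_for(true_labels, predicted):
    model = gs.TrainedModel(
        family="KNN", best_params={"k": 1}, cv_accuracy=1.0, cv_record=[],
        estimator=_ConstModel(predicted), classes=np.array([1, 2, 3, 4]))
    table = make_table(np.zeros((len(true_labels), 3)),
                       labels=np.asarray(true_labels))
    return gs.evaluate(model, table, "prediction")


class TestEvaluate:
    def test_all_correct_gives_100(self):
        y = np.tile([1, 2, 3, 4], 10)
        report = _report_for(y, y)
        assert report.overall == 100.0
        assert all(v == 100.0 for v in report.per_class.values())

    def test_395_of_400_gives_98_75(self):
        """The percent arithmetic: 395 correct of 400 -> 98.75% overall."""
        y = np.repeat([1, 2, 3, 4], 100)
        pred = y.copy()
        pred[:5] = 2  # five class-1 kernels misread
        report = _report_for(y, pred)
        assert report.overall == pytest.approx(98.75, abs=1e-12)
        assert report.per_class[1] == pytest.approx(95.0, abs=1e-12)

    def test_confusion_identities(self):
        rng = np.random.default_rng(3)
        y = rng.integers(1, 5, 80)
        pred = rng.integers(1, 5, 80)
        report = _report_for(y, pred)
        cm = report.confusion
        assert np.trace(cm) / cm.sum() == pytest.approx(
            report.overall / 100.0, abs=1e-12)
        for i, c in enumerate(report.classes):
            assert cm[i].sum() == (y == c).sum()  # row sums = support

    def test_unseen_label_rejected(self):
        model = gs.TrainedModel(
            family="KNN", best_params={"k": 1}, cv_accuracy=1.0, cv_record=[],
            estimator=_ConstModel(np.ones(4, int)), classes=np.array([1, 2]))
        table = make_table(np.zeros((4, 3)), labels=np.array([1, 2, 3, 1]))
        with pytest.raises(ValueError, match="training classes"):
            gs.evaluate(model, table, "prediction")


@pytest.fixture(scope="module")
def small_report():
    table = gs.trim_bands(
        gs.simulate_spectra_table(gs.SceneConfig(rng_seed=0,
                                                 grains_per_class=20)),
        931.8, 1653.8)
    return table, gs.run_grid(
        table, preprocessors=("raw", "msc"), selectors=("full", "nca"),
        families=("DT", "SVM"), seed=0)


class TestRunGridSmall:
    """Structural checks on a reduced grid (full 48-cell run lives in the
    acceptance suite)."""

    def test_shape_and_columns(self, small_report):
        _, report = small_report
        df = report.to_dataframe()
        assert len(df) == 2 * 2 * 2
        assert {"parameter", "cal_overall", "pred_overall", "pred_class_1",
                "pred_class_4"} <= set(df.columns)
        assert (df.status == "ok").all()

    def test_raw_full_cell_equals_direct_tuning(self, small_report):
        """The raw x full cell is the identity path: it must match tuning
        directly on the trimmed table with the same split and seed."""
        table, report = small_report
        cell = report.cell("raw", "full", "SVM")
        cal, pred = gs.split_calibration_prediction(table, (3, 1), seed=0)
        model = gs.tune_train(cal, default_spec("SVM", rng_seed=0))
        direct = gs.evaluate(model, pred, "prediction")
        assert cell.parameter == model.parameter_label
        assert cell.pred_report.overall == pytest.approx(direct.overall)

    def test_confusion_identities_in_every_cell(self, small_report):
        _, report = small_report
        for cell in report.cells:
            for rep in (cell.cal_report, cell.pred_report):
                cm = rep.confusion
                assert np.trace(cm) / cm.sum() == pytest.approx(
                    rep.overall / 100.0, abs=1e-12)

    def test_selector_failure_marks_cells_and_continues(self):
        table = gs.trim_bands(
            gs.simulate_spectra_table(gs.SceneConfig(rng_seed=0,
                                                     grains_per_class=20)),
            931.8, 1653.8)
        # spa_m_max beyond the rank budget of 60 calibration rows fails the
        # spa cells cleanly while the full cells proceed
        report = gs.run_grid(
            table, preprocessors=("raw",), selectors=("spa", "full"),
            families=("KNN",), seed=0, spa_m_max=60)
        df = report.to_dataframe()
        assert df[df.selector == "spa"].status.tolist() == ["failed"]
        assert df[df.selector == "full"].status.tolist() == ["ok"]
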