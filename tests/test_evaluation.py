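import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rehabhar import (
    CNNConfig,
    ConfusionMatrix,
    ExerciseClass,
    Grouping,
    Regime,
    SensorSubset,
    ablation_table,
    check_row_totals,
    compute_accuracy,
    cross_validate,
    kfold_split,
    run_ablation,
    sample_subject_profile,
    simulate_training_acquisition,
)

ROW_COUNTS = [1224, 1120, 1024, 1108, 1125]  # per-class window counts


def cm_with_correct(correct_per_class):
    """5x5 confusion with the given diagonal; each class's errors are
    dumped into one off-diagonal cell."""
    counts = np.zeros((5, 5), dtype=int)
    for i, (row_total, corr) in enumerate(zip(ROW_COUNTS, correct_per_class)):
        counts[i, i] = corr
        counts[i, (i + 1) % 5] = row_total - corr
    return ConfusionMatrix(counts, list(ExerciseClass))


class TestComputeAccuracy:
    @pytest.mark.parametrize(
        "correct,expected_pct",
        [(5590, 99.80), (5496, 98.13), (5381, 96.07)],
    )
    def test_overall_accuracy_fractions(self, correct, expected_pct):
        deficit = 5601 - correct
        diag = list(ROW_COUNTS)
        diag[1] -= deficit
        cm = cm_with_correct(diag)
        overall, _ = compute_accuracy(cm)
        assert cm.total == 5601
        assert round(100 * overall, 2) == expected_pct

    def test_per_class_accuracy_fraction(self):
        diag = list(ROW_COUNTS)
        diag[2] = 886  # wall push: 886 correct of 1024
        cm = cm_with_correct(diag)
        _, per_class = compute_accuracy(cm)
        assert round(100 * per_class[ExerciseClass.WALL_PUSH], 1) == 86.5

    def test_row_counts_sum_to_total(self):
        assert check_row_totals(ROW_COUNTS, 5601)
        assert not check_row_totals(ROW_COUNTS, 5600)

    def test_diagonal_matrix_is_perfect(self):
        cm = cm_with_correct(ROW_COUNTS)
        overall, per_class = compute_accuracy(cm)
        assert overall == 1.0
        assert all(v == 1.0 for v in per_class.values())

    def test_empty_matrix_rejected(self):
        cm = ConfusionMatrix(np.zeros((5, 5), dtype=int), list(ExerciseClass))
        with pytest.raises(ValueError, match="empty"):
            compute_accuracy(cm)

    def test_binary_case_reduces_to_tp_tn_formula(self):
        tp, tn, fp, fn = 37, 51, 6, 9
        cm = ConfusionMatrix(
            np.array([[tn, fp], [fn, tp]]),
            [ExerciseClass.NO_EXERCISE, ExerciseClass.WALL_PUSH],
        )
        overall, _ = compute_accuracy(cm)
        assert overall == (tp + tn) / (tp + tn + fp + fn)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_weighted_per_class_equals_overall(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 50, size=(5, 5))
        counts[0, 0] += 1  # non-empty
        cm = ConfusionMatrix(counts, list(ExerciseClass))
        overall, per_class = compute_accuracy(cm)
        rows = cm.row_totals
        weighted = sum(
            per_class[c] * rows[i]
            for i, c in enumerate(cm.classes)
            if rows[i] > 0
        )
        assert abs(weighted / cm.total - overall) < 1e-12

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_matches_naive_recount_of_pairs(self, seed):
        rng = np.random.default_rng(seed)
        true = rng.integers(0, 5, size=200)
        pred = rng.integers(0, 5, size=200)
        cm = ConfusionMatrix.from_pairs(true, pred)
        overall, _ = compute_accuracy(cm)
        assert overall == np.mean(true == pred)


class TestKFold:
    def test_partition_property(self, tiny_windows):
        folds = kfold_split(tiny_windows, k=5, seed=0)
        all_idx = np.sort(np.concatenate(folds))
        np.testing.assert_array_equal(all_idx, np.arange(len(tiny_windows)))

    def test_stratification_on_balanced_classes(self):
        from conftest import make_toy_windows

        windows = make_toy_windows(n_per_class=50, seed=0)  # 100 windows
        folds = kfold_split(windows, k=5, seed=1)
        global_frac = 0.5
        for fold in folds:
            assert len(fold) == 20
            labels = [int(windows[i].label) for i in fold]
            frac = np.mean(np.array(labels) == 0)
            assert abs(frac - global_frac) <= 1 / len(fold)

    def test_same_seed_same_folds(self, tiny_windows):
        f1 = kfold_split(tiny_windows, k=5, seed=3)
        f2 = kfold_split(tiny_windows, k=5, seed=3)
        for a, b in zip(f1, f2):
            np.testing.assert_array_equal(a, b)

    def test_k_below_two_rejected(self, tiny_windows):
        with pytest.raises(ValueError, match="k must be"):
            kfold_split(tiny_windows, k=1)

    def test_segment_grouping_keeps_runs_together(self, tiny_windows):
        folds = kfold_split(tiny_windows, k=3, seed=0, grouping=Grouping.SEGMENT)
        fold_of = {}
        for fi, fold in enumerate(folds):
            for i in fold:
                fold_of[i] = fi
        by_segment = {}
        for i, w in enumerate(tiny_windows):
            by_segment.setdefault((w.subject_id, w.segment), set()).add(fold_of[i])
        assert all(len(fs) == 1 for fs in by_segment.values())


@pytest.fixture(scope="module")
def report(tiny_windows):
    return cross_validate(
        tiny_windows, SensorSubset.ACCEL_GYRO, CNNConfig(epochs=8, seed=0),
        k=5, seed=0,
    )


@pytest.fixture(scope="module")
def grid(sim_config):
    sessions = {
        s: simulate_training_acquisition(
            sample_subject_profile(sim_config, s), sim_config, reps=2, sessions=1
        )
        for s in ("S01", "S02")
    }
    return run_ablation(
        sessions, "S01", config=CNNConfig(epochs=3, seed=0), k=3, seed=0
    )


class TestCrossValidate:
    def test_pooled_confusion_conserves_windows(self, report, tiny_windows):
        assert report.pooled.total == len(tiny_windows)

    def test_pooled_equals_sum_of_folds(self, report):
        summed = sum((cm.counts for cm in report.fold_confusions),
                     np.zeros((5, 5), dtype=int))
        np.testing.assert_array_equal(report.pooled.counts, summed)

    def test_accuracy_matches_recount(self, report):
        overall, _ = compute_accuracy(report.pooled)
        assert report.overall_accuracy == overall

    def test_fold_assignment_covers_all_windows(self, report, tiny_windows):
        assert set(report.fold_assignment) == set(range(5))
        assert len(report.fold_assignment) == len(tiny_windows)


class TestAblation:
    def test_grid_has_six_cells(self, grid):
        assert len(grid) == 6
        assert {key[0] for key in grid} == set(Regime)
        assert {key[1] for key in grid} == set(SensorSubset)

    def test_each_cell_reports_five_classes_plus_total(self, grid):
        for report in grid.values():
            row = report.summary_row()
            assert len(row) == 6 and "TOTAL" in row

    def test_total_regime_pools_all_subjects(self, grid):
        personal = grid[(Regime.PERSONAL, SensorSubset.ACCEL)].pooled.total
        total = grid[(Regime.TOTAL, SensorSubset.ACCEL)].pooled.total
        assert total == 2 * personal

    def test_summary_table_shape(self, grid):
        table = ablation_table(grid)
        assert table.shape == (6, 6)
        assert list(table.index)[-1] == "Total"
        assert ((table >= 0) & (table <= 100)).all().all()

    def test_single_subject_total_regime_rejected(self, sim_config):
        sessions = {
            "S01": simulate_training_acquisition(
                sample_subject_profile(sim_config, "S01"), sim_config, reps=2, sessions=1
            )
        }
        with pytest.raises(ValueError, match="2 subjects"):
            run_ablation(sessions, "S01")
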