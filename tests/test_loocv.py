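import dataclasses

import numpy as np
import pytest

import wmsvm as w
from wmsvm.errors import CohortError, DimensionError, ParameterError

from conftest import make_cohort


def _perturb_subject(cohort, index, amount=0.03):
    volumes = list(cohort.volumes)
    vol = volumes[index]
    volumes[index] = w.ScalarVolume(vol.values + amount, voxel_size=vol.voxel_size)
    return dataclasses.replace(cohort, volumes=tuple(volumes))


class TestLoocvRun:
    def test_each_subject_left_out_exactly_once(self, null_cohort):
        mask = w.build_mask(null_cohort.volumes)
        folds = w.loocv_run(null_cohort, mask, k=10)
        assert [f.left_out_subject for f in folds] == list(null_cohort.subject_ids)
        assert all(f.k == 10 for f in folds)

    def test_perturbing_left_out_subject_changes_nothing_trained(self, null_cohort):
        mask = w.build_mask(null_cohort.volumes)
        baseline = w.loocv_run(null_cohort, mask, k=20)
        i = 5
        perturbed = w.loocv_run(_perturb_subject(null_cohort, i), mask, k=20)
        np.testing.assert_array_equal(perturbed[i].selected_features, baseline[i].selected_features)
        np.testing.assert_array_equal(perturbed[i].scaler.means, baseline[i].scaler.means)
        np.testing.assert_array_equal(perturbed[i].scaler.sds, baseline[i].scaler.sds)
        np.testing.assert_array_equal(perturbed[i].w, baseline[i].w)
        assert perturbed[i].b == baseline[i].b
        assert perturbed[i].decision_value != baseline[i].decision_value

    def test_strong_effect_classified_perfectly(self, effect_cohort):
        mask = w.build_mask(effect_cohort.volumes)
        folds = w.loocv_run(effect_cohort, mask, k=20)
        assert all(f.predicted_label == f.true_label for f in folds)

    def test_loocv_accuracy_consistent_with_folds(self, effect_cohort):
        mask = w.build_mask(effect_cohort.volumes)
        fm = w.volumes_to_matrix(effect_cohort, mask)
        folds = w.loocv_run(effect_cohort, mask, k=20)
        acc = np.mean([f.predicted_label == f.true_label for f in folds])
        assert w.loocv_accuracy(fm.X, effect_cohort.labels, 20) == pytest.approx(acc)

    def test_too_small_groups_rejected(self):
        cohort = make_cohort(n_controls=2, n_patients=4, grid=5)
        mask = w.build_mask(cohort.volumes)
        with pytest.raises(CohortError):
            w.loocv_run(cohort, mask, k=5)

    def test_k_above_m_rejected(self, null_cohort):
        mask = w.build_mask(null_cohort.volumes)
        with pytest.raises(ParameterError):
            w.loocv_run(null_cohort, mask, k=mask.n_voxels + 1)


class TestKSweep:
    def test_small_grid(self, effect_cohort):
        mask = w.build_mask(effect_cohort.volumes)
        sweep = w.k_sweep(effect_cohort, mask, k_max=30, step=10)
        assert sweep.k_grid.tolist() == [10, 20, 30]
        assert len(sweep.fold_results) == 3

    def test_accuracy_matches_confusion_metrics(self, effect_cohort):
        mask = w.build_mask(effect_cohort.volumes)
        sweep = w.k_sweep(effect_cohort, mask, k_max=30, step=15)
        for idx in range(len(sweep.k_grid)):
            cm = w.confusion_from_folds(sweep.fold_results[idx])
            assert sweep.accuracies[idx] == pytest.approx(cm.accuracy)
            assert sweep.sensitivities[idx] == pytest.approx(cm.sensitivity)
            assert sweep.specificities[idx] == pytest.approx(cm.specificity)

    def test_grid_truncates_at_m(self, effect_cohort):
        mask = w.build_mask(effect_cohort.volumes)
        m = mask.n_voxels
        sweep = w.k_sweep(effect_cohort, mask, k_max=10 * m, step=m)
        assert sweep.k_grid.tolist() == [m]
        with pytest.raises(ParameterError):
            w.k_sweep(effect_cohort, mask, k_max=10 * m, step=m, truncate_at_m=False)

    def test_null_cohort_peak_accuracy_stays_near_chance(self):
        cohort = make_cohort(n_controls=8, n_patients=8, delta=0.0, seed=0)
        mask = w.build_mask(cohort.volumes)
        sweep = w.k_sweep(cohort, mask, k_max=64, step=16, keep_folds=False)
        # binomial 95% band around 0.5 for n=16 subjects
        assert 4 / 16 <= sweep.accuracies.max() <= 12 / 16


class TestSelectOptimalK:
    def test_unique_maximum(self):
        sweep = w.SweepResult(
            k_grid=np.arange(100, 1001, 100),
            accuracies=np.r_[np.full(4, 0.6), 0.9, np.full(5, 0.6)],
            sensitivities=np.zeros(10),
            specificities=np.zeros(10),
        )
        assert w.select_optimal_k(sweep) == 500

    def test_even_length_run_snaps_down(self):
        sweep = w.SweepResult(
            k_grid=np.array([100, 200, 300]),
            accuracies=np.array([0.9, 0.9, 0.5]),
            sensitivities=np.zeros(3),
            specificities=np.zeros(3),
        )
        assert w.select_optimal_k(sweep) == 100

    def test_earliest_of_equally_long_runs_wins(self):
        sweep = w.SweepResult(
            k_grid=np.arange(100, 701, 100),
            accuracies=np.array([0.9, 0.9, 0.5, 0.9, 0.9, 0.5, 0.5]),
            sensitivities=np.zeros(7),
            specificities=np.zeros(7),
        )
        assert w.select_optimal_k(sweep) == 100

    def test_longest_run_beats_earlier_shorter_run(self):
        sweep = w.SweepResult(
            k_grid=np.arange(100, 701, 100),
            accuracies=np.array([0.9, 0.5, 0.9, 0.9, 0.9, 0.5, 0.5]),
            sensitivities=np.zeros(7),
            specificities=np.zeros(7),
        )
        assert w.select_optimal_k(sweep) == 400


class TestAverageWeightMap:
    @staticmethod
    def _fold(selected, weights, subject="s"):
        return w.FoldResult(
            left_out_subject=subject,
            true_label=1,
            decision_value=0.0,
            predicted_label=-1,
            selected_features=np.asarray(selected),
            w=np.asarray(weights, dtype=float),
            b=0.0,
            scaler=w.Scaler(means=np.zeros(len(selected)), sds=np.ones(len(selected))),
        )

    @pytest.fixture
    def mask(self):
        return w.BinaryMask.from_array(np.ones((2, 2, 2), dtype=bool))

    def test_identical_folds_average_to_themselves(self, mask):
        folds = [self._fold([0, 3], [0.5, -0.2]) for _ in range(4)]
        vol = w.average_weight_map(folds, mask)
        flat = vol.values.ravel()
        assert flat[0] == pytest.approx(0.5)
        assert flat[3] == pytest.approx(-0.2)
        assert flat[1] == flat[2] == 0.0

    def test_partially_selected_voxel_diluted_by_fold_count(self, mask):
        folds = [self._fold([0, 1], [1.0, 0.4]), self._fold([0, 2], [1.0, 0.8])]
        flat = w.average_weight_map(folds, mask).values.ravel()
        assert flat[1] == pytest.approx(0.2)  # selected by 1 of 2 folds
        assert flat[2] == pytest.approx(0.4)
        assert flat[0] == pytest.approx(1.0)

    def test_out_of_mask_fill(self):
        arr = np.zeros((2, 2, 2), dtype=bool)
        arr[0, 0, 0] = True
        mask = w.BinaryMask.from_array(arr)
        vol = w.average_weight_map([self._fold([0], [0.7])], mask, fill=np.nan)
        assert vol.values[0, 0, 0] == pytest.approx(0.7)
        assert np.isnan(vol.values[1, 1, 1])

    def test_inconsistent_k_rejected(self, mask):
        with pytest.raises(DimensionError):
            w.average_weight_map([self._fold([0], [1.0]), self._fold([0, 1], [1.0, 1.0])], mask)
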