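"""Preparation and clustering: masking, percent signal change, k-means
sub-regions, extraction, run averaging."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import adjusted_rand_score

from sapm.prep import (
    ClusterBalanceWarning,
    average_runs,
    cluster_region,
    extract_subregion_timecourses,
    mask_initial_volumes,
    to_percent_signal_change,
    MASK_DEFAULTS,
)
from sapm.synth import simulate_voxels


class TestMasking:
    def test_forced_example(self):
        assert mask_initial_volumes(np.array([1., 2, 3, 4, 5]), 3).tolist() == [4, 4, 4, 4, 5]

    def test_zero_replacement_is_identity(self):
        assert mask_initial_volumes(np.array([7., 9]), 0).tolist() == [7, 9]

    def test_defaults_match_acquisition_types(self):
        assert MASK_DEFAULTS == {"brain": 3, "brainstem_cord": 2}

    def test_too_many_replacements_rejected(self):
        with pytest.raises(ValueError):
            mask_initial_volumes(np.zeros(4), 4)

    @given(st.integers(0, 9))
    @settings(deadline=None)
    def test_idempotent_and_length_preserving(self, n):
        rng = np.random.default_rng(n)
        x = rng.standard_normal(10)
        once = mask_initial_volumes(x, n)
        assert once.shape == x.shape
        assert np.array_equal(mask_initial_volumes(once, n), once)


class TestPercentSignalChange:
    def test_constant_series_maps_to_zeros(self):
        assert np.allclose(to_percent_signal_change(np.full(5, 42.0)), 0.0)

    def test_forced_arithmetic(self):
        assert to_percent_signal_change(np.array([90., 110.])).tolist() == [-10.0, 10.0]

    def test_output_mean_is_zero(self, rng):
        x = 1000 + rng.standard_normal(50)
        assert abs(to_percent_signal_change(x).mean()) < 1e-10

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            to_percent_signal_change(np.array([-1.0, 1.0]))


class TestClustering:
    def test_separable_subregions_recovered_exactly(self, rng):
        sub = 5.0 * rng.standard_normal((5, 40))
        vox = simulate_voxels(sub, voxels_per_subregion=6, within_sd=0.0, seed=0)
        asg = cluster_region(vox.values, k=5, seed=0)
        assert adjusted_rand_score(vox.labels, asg.labels) == 1.0

    def test_seed_determinism(self, rng):
        sub = rng.standard_normal((5, 40))
        vox = simulate_voxels(sub, 8, 0.3, seed=1)
        a = cluster_region(vox.values, seed=0)
        b = cluster_region(vox.values, seed=0)
        assert np.array_equal(a.labels, b.labels)

    def test_agreement_with_ground_truth_above_090(self, rng):
        sub = rng.standard_normal((5, 60))
        vox = simulate_voxels(sub, 10, within_sd=0.1, seed=2)
        asg = cluster_region(vox.values, k=5, seed=0)
        assert adjusted_rand_score(vox.labels, asg.labels) > 0.9

    def test_voxel_order_invariance_up_to_relabeling(self, rng):
        sub = rng.standard_normal((5, 40))
        vox = simulate_voxels(sub, 6, 0.05, seed=3)
        perm = rng.permutation(vox.values.shape[0])
        a = cluster_region(vox.values, seed=0)
        b = cluster_region(vox.values[perm], seed=0)
        assert adjusted_rand_score(a.labels[perm], b.labels) == 1.0

    def test_fewer_voxels_than_k_rejected(self, rng):
        with pytest.raises(ValueError):
            cluster_region(rng.standard_normal((3, 10)), k=5)

    def test_unbalanced_partition_warns(self, rng):
        # one far-away voxel and many near-identical ones force imbalance
        base = np.tile(rng.standard_normal(20), (9, 1)) + 0.01 * rng.standard_normal((9, 20))
        outlier = 50 + rng.standard_normal((1, 20))
        with pytest.warns(ClusterBalanceWarning):
            cluster_region(np.vstack([base, outlier]), k=2, seed=0)


class TestExtraction:
    def test_single_voxel_subregions_reproduce_the_voxel(self, rng):
        sub = rng.standard_normal((5, 30))
        vox = simulate_voxels(sub, voxels_per_subregion=1, within_sd=0.0, seed=0)
        asg = cluster_region(vox.values, k=5, seed=0)
        out = extract_subregion_timecourses(vox.values, asg)
        # each output equals one (percent-signal-changed) voxel
        psc = to_percent_signal_change(vox.values)
        for row in out:
            assert any(np.allclose(row, v, atol=1e-9) for v in psc)

    def test_zero_noise_recovers_generating_signal(self, rng):
        sub = rng.standard_normal((5, 30))
        sub -= sub.mean(axis=1, keepdims=True)
        vox = simulate_voxels(sub, 7, within_sd=0.0, seed=0)
        asg = cluster_region(vox.values, k=5, seed=0)
        out = extract_subregion_timecourses(vox.values, asg)
        for s in sub:
            assert any(np.allclose(row, s, atol=1e-6) for row in out)

    def test_averaging_reduces_noise_variance(self, rng):
        """Residual variance after averaging n voxels is ~1/n of one voxel's."""
        n_vox, T = 25, 2000
        signal = np.zeros((1, T))
        vox = simulate_voxels(signal, n_vox, within_sd=1.0, seed=5)
        asg = cluster_region(vox.values, k=1, seed=0)
        out = extract_subregion_timecourses(vox.values, asg)
        single = to_percent_signal_change(vox.values[0])
        ratio = out[0].var() / single.var()
        assert ratio == pytest.approx(1.0 / n_vox, rel=0.35)

    def test_gain_invariance_of_extract(self, rng):
        """Percent-signal-change extraction removes any multiplicative gain."""
        sub = rng.standard_normal((3, 20))
        vox = simulate_voxels(sub, 4, 0.1, seed=6)
        asg = cluster_region(vox.values, k=3, seed=0)
        a = extract_subregion_timecourses(vox.values, asg)
        b = extract_subregion_timecourses(3.7 * vox.values, asg)
        assert np.allclose(a, b, atol=1e-9)


class TestAverageRuns:
    def test_single_run_mean_is_itself_sem_zero(self, rng):
        x = rng.standard_normal((3, 10))
        mean, sem = average_runs([x])
        assert np.array_equal(mean, x) and np.allclose(sem, 0.0)

    def test_two_run_mean(self):
        mean, _ = average_runs([np.array([0., 2.]), np.array([2., 0.])])
        assert mean.tolist() == [1.0, 1.0]

    def test_identical_runs_have_zero_sem(self, rng):
        x = rng.standard_normal(8)
        _, sem = average_runs([x, x, x])
        assert np.allclose(sem, 0.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            average_runs([np.zeros(4), np.zeros(5)])
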