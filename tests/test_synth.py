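"""Synthetic-data generator: paradigm arithmetic, latent construction,
forward-model consistency, determinism, and group structure."""

import numpy as np
import pytest

from sapm.core import build_matrices, default_D, solve_forward
from sapm.design import ParadigmSpec, make_paradigm
from sapm.synth import (
    SimulationConfig,
    generate_latents,
    make_subregion_timecourses,
    simulate_bold,
    simulate_pupil,
    simulate_voxels,
    PUPIL_DEFAULTS,
)


class TestParadigm:
    def test_brain_defaults_give_135_volumes(self):
        spec, ind = make_paradigm("Pain")
        assert spec.n_volumes == 135
        assert ind.shape == (135,)

    def test_brainstem_defaults_give_40_volumes(self):
        spec, _ = make_paradigm("Pain", TR=6.75)
        assert spec.n_volumes == 40

    def test_five_runs_per_condition_give_200_brainstem_volumes(self):
        spec, _ = make_paradigm("Pain", TR=6.75)
        assert 5 * spec.n_volumes == 200

    def test_stimulation_block_is_30_seconds(self):
        spec, ind = make_paradigm("Pain")
        assert spec.stimulation_duration == 30.0
        assert spec.run_duration == 4.5 * 60
        # indicator covers the block, nothing before 120 s or after 150 s
        t = spec.times
        assert not ind[t < 120].any() and not ind[t >= 150].any()
        assert ind[(t >= 120) & (t < 150)].any()

    def test_no_pain_run_has_no_stimulation(self):
        _, ind = make_paradigm("NoPain")
        assert not ind.any()

    def test_non_integer_volume_count_rejected(self):
        with pytest.raises(ValueError, match="volume count"):
            ParadigmSpec(run_duration=271.0, TR=2.0)

    def test_stimulation_exceeding_run_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            ParadigmSpec(run_duration=140.0, TR=2.0)


class TestLatents:
    def test_zero_amplitudes_give_zero_latents(self, demo_net, pain_paradigm):
        cfg = SimulationConfig(network=demo_net, event_amplitude=0.0,
                               drift_amplitude=0.0, rise_latent_amplitude=0.0)
        lat = generate_latents(pain_paradigm, cfg, seed=0)
        assert np.allclose(lat, 0.0)

    def test_same_seed_reproduces_latents(self, brain_net, pain_paradigm):
        cfg = SimulationConfig(network=brain_net)
        a = generate_latents(pain_paradigm, cfg, seed=7)
        b = generate_latents(pain_paradigm, cfg, seed=7)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, generate_latents(pain_paradigm, cfg, seed=8))

    def test_unit_variance_after_construction(self, brain_net, pain_paradigm):
        cfg = SimulationConfig(network=brain_net)
        lat = generate_latents(pain_paradigm, cfg, seed=3)
        assert np.allclose(lat.std(axis=1), 1.0)
        assert np.allclose(lat.mean(axis=1), 0.0, atol=1e-12)

    def test_pain_latents_peak_shortly_after_stimulation_onset(self, brain_net, pain_paradigm):
        """Some latent carries a local maximum within 15 s of stimulation onset."""
        cfg = SimulationConfig(network=brain_net, drift_amplitude=0.0)
        lat = generate_latents(pain_paradigm, cfg, seed=1)
        t = pain_paradigm.times
        win = (t > pain_paradigm.stimulus_onset) & (t <= pain_paradigm.stimulus_onset + 15)
        found = False
        for x in lat:
            i = np.flatnonzero(win)[np.argmax(x[win])]
            if 0 < i < len(x) - 1 and x[i] >= x[i - 1] and x[i] >= x[i + 1]:
                found = True
        assert found


class TestSimulateBold:
    def test_forward_equation_consistency(self, demo_net, pain_paradigm):
        """Noise-free network signal satisfies the fixed-point equations to
        machine precision (cross-module oracle)."""
        cfg = SimulationConfig(network=demo_net, noise_sd=0.0,
                               n_participants={"HC": 1}, n_runs=1)
        study = simulate_bold(cfg, pain_paradigm, seed=5)
        run = study.runs[0]
        mats = build_matrices(demo_net, cfg.true_D, cfg.true_B)
        S_out, S_in = solve_forward(mats, run.latents)
        assert np.allclose(S_in, run.network_signal, atol=1e-12)
        # observation = network signal + rise (+ zero noise)
        assert np.allclose(run.values, run.network_signal + run.rise, atol=1e-12)

    def test_no_propagation_when_B_zero(self, demo_net, pain_paradigm):
        """With all B = 0 the signal appears only at latent-target regions,
        proportional to their latent drive."""
        cfg = SimulationConfig(network=demo_net, true_B=np.zeros(len(demo_net.connections)),
                               noise_sd=0.0, rise_amplitude=0.0,
                               n_participants={"HC": 1}, n_runs=1)
        study = simulate_bold(cfg, pain_paradigm, seed=2)
        run = study.runs[0]
        targets = {t for _, t in demo_net.latents}
        for i, r in enumerate(demo_net.regions):
            if r in targets:
                lat_idx = [k for k, (_, t) in enumerate(demo_net.latents) if t == r][0]
                d = cfg.true_D[len(demo_net.edges) + lat_idx]
                assert np.allclose(run.values[i], d * run.latents[lat_idx], atol=1e-12)
            else:
                assert np.allclose(run.values[i], 0.0, atol=1e-12)

    def test_linearity_in_latent_drive(self, demo_net, pain_paradigm):
        """Scaling all latents by c scales all noise-free signals by c."""
        cfg = SimulationConfig(network=demo_net, noise_sd=0.0)
        lat = generate_latents(pain_paradigm, cfg, seed=4)
        mats = build_matrices(demo_net, cfg.true_D, cfg.true_B)
        _, s1 = solve_forward(mats, lat)
        _, s3 = solve_forward(mats, 3.0 * lat)
        assert np.allclose(s3, 3.0 * s1, atol=1e-10)

    def test_determinism_and_group_sizes(self, demo_net, pain_paradigm):
        cfg = SimulationConfig(network=demo_net, n_participants={"FM": 2, "HC": 3},
                               n_runs=2, seed=11)
        a = simulate_bold(cfg, pain_paradigm)
        b = simulate_bold(cfg, pain_paradigm)
        assert len(a.runs) == (2 + 3) * 2
        assert all(np.array_equal(x.values, y.values) for x, y in zip(a.runs, b.runs))
        groups = {r.group for r in a.runs}
        assert groups == {"FM", "HC"}

    def test_fm_rise_is_doubled(self, demo_net, pain_paradigm):
        cfg = SimulationConfig(network=demo_net, noise_sd=0.0,
                               n_participants={"FM": 1, "HC": 1}, n_runs=1)
        study = simulate_bold(cfg, pain_paradigm, seed=1)
        fm = study.select(group="FM")[0]
        hc = study.select(group="HC")[0]
        assert np.allclose(fm.rise, 2.0 * hc.rise)

    def test_unstable_network_rejected(self, demo_net, pain_paradigm):
        b = np.full(len(demo_net.connections), 50.0)
        with pytest.raises(ValueError, match="spectral radius"):
            cfg = SimulationConfig(network=demo_net, true_B=b)
            simulate_bold(cfg, pain_paradigm, seed=0)


class TestVoxels:
    def test_zero_within_noise_gives_identical_voxels(self, rng):
        sub = rng.standard_normal((5, 30))
        vox = simulate_voxels(sub, voxels_per_subregion=4, within_sd=0.0, seed=0)
        for j in range(5):
            block = vox.values[j * 4:(j + 1) * 4]
            assert np.allclose(block, block[0])

    def test_voxel_counts_and_labels(self, rng):
        sub = rng.standard_normal((5, 20))
        vox = simulate_voxels(sub, voxels_per_subregion=10, within_sd=0.1, seed=0)
        assert vox.values.shape == (50, 20)
        assert set(vox.labels) == {1, 2, 3, 4, 5}
        assert np.bincount(vox.labels)[1:].tolist() == [10] * 5

    def test_planted_subregion_carries_the_region_signal(self, demo_net, rng):
        tc = rng.standard_normal((demo_net.n_regions, 25))
        subs, planted = make_subregion_timecourses(tc, demo_net, k=4, seed=3)
        for i, r in enumerate(demo_net.regions):
            assert np.array_equal(subs[r][planted[r]], tc[i])


class TestPupil:
    def test_reference_segments_present_at_both_ends(self):
        tr = simulate_pupil(PUPIL_DEFAULTS["HC"], 1, seed=0, fs=50.0)[0]
        s = tr.screen_state
        assert s[0] == "white" and s[-1] == "black"
        assert (s == "task").sum() > 0

    def test_zero_blink_rate_gives_no_missing_samples(self):
        tr = simulate_pupil(PUPIL_DEFAULTS["FM"], 2, seed=1, fs=50.0)
        assert all(np.isfinite(t.area).all() for t in tr)

    def test_same_seed_identical_traces(self):
        a = simulate_pupil(PUPIL_DEFAULTS["FM"], 3, seed=9, fs=50.0)
        b = simulate_pupil(PUPIL_DEFAULTS["FM"], 3, seed=9, fs=50.0)
        assert all(np.array_equal(x.area, y.area) for x, y in zip(a, b))
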