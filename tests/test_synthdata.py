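"""Stimulus, schedule, EEG and BOLD generators: structure and determinism."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from musedecode import fmri_select as fm
from musedecode import synthdata as sd


class TestGenerateMusic:
    def test_default_set_structure(self):
        stim = sd.generate_music(36, 40.0, 1000.0, (60, 180), seed=1)
        assert len(stim) == 36
        assert all(len(p.waveform) == 40_000 for p in stim.pieces)
        targets = {p.affect_target for p in stim.pieces}
        assert len(targets) == 9  # 9 valence/arousal classes, 4 pieces each
        counts = [sum(p.affect_target == t for p in stim.pieces) for t in targets]
        assert counts == [4] * 9

    def test_metronome_inter_onset_interval_exact(self):
        stim = sd.generate_music(1, 1.0, 100.0, (60, 60), seed=0)
        onsets = stim.pieces[0].onsets_s
        assert np.allclose(np.diff(onsets), 1.0)
        assert stim.pieces[0].tempo_bpm == pytest.approx(60.0)

    def test_seeded_determinism(self):
        a = sd.generate_music(3, 10.0, 1000.0, (90, 90), seed=7)
        b = sd.generate_music(3, 10.0, 1000.0, (90, 90), seed=7)
        for pa, pb in zip(a.pieces, b.pieces):
            assert np.array_equal(pa.waveform, pb.waveform)

    def test_invalid_configuration_errors(self):
        with pytest.raises(ValueError, match="tempo"):
            sd.generate_music(1, 10.0, 100.0, (10, 60), seed=0)
        with pytest.raises(ValueError, match="duration"):
            sd.generate_music(1, -1.0, 100.0, (60, 120), seed=0)

    def test_waveforms_finite_and_nonconstant(self):
        stim = sd.generate_music(4, 5.0, 500.0, (60, 180), seed=3)
        for p in stim.pieces:
            assert np.all(np.isfinite(p.waveform))
            assert np.ptp(p.waveform) > 0


@pytest.fixture(scope="module")
def stimuli():
    return sd.generate_music(36, 2.0, 100.0, (60, 180), seed=1)


class TestGenerateSchedule:
    def test_default_36_trials_pieces_unique(self, stimuli):
        sched = sd.generate_schedule(3, 12, stimuli, seed=2,
                                     trial_duration_s=40.0)
        assert len(sched) == 36
        used = [t.piece_id for t in sched.music_trials()]
        assert len(used) == len(set(used))  # each piece at most once
        assert len(sched.music_trials()) == 30

    def test_intertrial_gap_arithmetic(self, stimuli):
        """Consecutive onsets differ by >= task + break + minimum fixation."""
        sched = sd.generate_schedule(3, 12, stimuli, seed=5,
                                     trial_duration_s=40.0)
        for run in sched.runs:
            onsets = [t.onset for t in sched.trials if t.run == run]
            gaps = np.diff(onsets)
            assert np.all(gaps >= 40.0 + 0.5 + 1.0)
            assert np.all(gaps <= 40.0 + 0.5 + 3.0 + 1e-9)

    def test_single_trial_starts_after_fixation(self, stimuli):
        sched = sd.generate_schedule(1, 1, stimuli, seed=0, type_mix=(1, 0, 0))
        (tr,) = sched.trials
        assert 1.0 <= tr.onset <= 3.0

    def test_too_few_pieces_errors(self):
        small = sd.generate_music(3, 2.0, 100.0, (60, 180), seed=1)
        with pytest.raises(ValueError, match="music trials"):
            sd.generate_schedule(3, 12, small, seed=0)
        # with replacement the same set is acceptable
        sched = sd.generate_schedule(3, 12, small, seed=0, replace=True)
        assert len(sched.music_trials()) == 30

    def test_schedule_conservation(self, stimuli):
        """Run length equals the sum of fixation + task + break intervals
        plus the post-run rest."""
        sched = sd.generate_schedule(2, 4, stimuli, seed=9, type_mix=(2, 1, 1),
                                     trial_duration_s=5.0, post_run_rest_s=10.0)
        for run in sched.runs:
            trials = [t for t in sched.trials if t.run == run]
            reconstructed = 0.0
            prev_end = 0.0
            for t in trials:
                fixation = t.onset - prev_end
                assert 1.0 <= fixation <= 3.0
                reconstructed += fixation + t.duration + 0.5
                prev_end = t.onset + t.duration + 0.5
            assert sched.run_lengths_s[run - 1] == pytest.approx(
                reconstructed + 10.0
            )

    @given(seed=st.integers(0, 10_000))
    def test_music_trials_always_carry_pieces(self, seed):
        stim = sd.generate_music(12, 1.0, 100.0, (60, 120), seed=0)
        sched = sd.generate_schedule(2, 5, stim, seed=seed, type_mix=(2, 2, 1),
                                     trial_duration_s=3.0)
        for t in sched.trials:
            if t.type == "reporting_only":
                assert t.piece_id is None
            else:
                assert t.piece_id is not None


@pytest.fixture(scope="module")
def tiny_session(coarse_lf_module):
    stim = sd.generate_music(4, 5.0, 500.0, (90, 150), seed=3)
    sched = sd.generate_schedule(1, 4, stim, seed=4, type_mix=(2, 1, 1),
                                 post_run_rest_s=2.0)
    return stim, sched


@pytest.fixture(scope="module")
def coarse_lf_module():
    from musedecode import headmodel as hm

    return hm.build_spherical_leadfield(
        hm.standard_sensor_array(), grid_spacing_mm=30.0
    )


class TestSimulateEEG:
    def test_zero_coupling_uncorrelated_with_envelope(self, tiny_session,
                                                      coarse_lf_module):
        stim, sched = tiny_session
        lf = coarse_lf_module
        # white sensor noise only, so the 3/sqrt(N) bound applies exactly
        cfg = sd.SimulationConfig(seed=0, fs_eeg=500.0, coupling_gain=0.0,
                                  source_noise_sd=0.0, sensor_noise_sd=1.0,
                                  n_background_sources=0)
        rec = sd.simulate_eeg(stim, sched, lf, lf.grid[[10, 40]], cfg)
        tr = sched.music_trials()[0]
        start = int(round(tr.onset * 500))
        n = int(round(tr.duration * 500))
        env = sd.music_envelope(stim.piece(tr.piece_id).waveform, 500.0, 8.0, 0.1)
        seg = rec.data[:, start : start + n]
        r = np.array(
            [np.corrcoef(ch, env[:n])[0, 1] for ch in seg]
        )
        assert np.abs(r).max() < 3.0 / np.sqrt(n)

    def test_single_source_rank_one(self, tiny_session, coarse_lf_module):
        stim, sched = tiny_session
        lf = coarse_lf_module
        cfg = sd.SimulationConfig(
            seed=1, fs_eeg=500.0, coupling_gain=2.0,
            sensor_noise_sd=0.0, n_background_sources=0,
        )
        rec = sd.simulate_eeg(stim, sched, lf, lf.grid[[20]], cfg)
        # every channel is a scalar multiple of one source time course
        u, s, _ = np.linalg.svd(rec.data, full_matrices=False)
        assert s[1] < 1e-8 * s[0]

    def test_forward_model_linearity(self, tiny_session, coarse_lf_module):
        """Scaling the stimuli scales the noiseless sensor data linearly."""
        stim, sched = tiny_session
        lf = coarse_lf_module
        cfg = sd.SimulationConfig(
            seed=2, fs_eeg=500.0, coupling_gain=3.0,
            sensor_noise_sd=0.0, source_noise_sd=0.0,
            n_background_sources=0,
        )
        rec1 = sd.simulate_eeg(stim, sched, lf, lf.grid[[15]], cfg)
        scaled = sd.StimulusSet(
            [
                sd.Piece(
                    p.piece_id, 0.5 * p.waveform, p.fs, p.duration_s,
                    p.affect_target, p.tempo_bpm, p.nominal_tempo_bpm,
                    p.onsets_s,
                )
                for p in stim.pieces
            ]
        )
        rec2 = sd.simulate_eeg(scaled, sched, lf, lf.grid[[15]], cfg)
        assert np.allclose(rec2.data, 0.5 * rec1.data, atol=1e-12)

    def test_coupled_channel_beats_phase_shuffled_null(self, tiny_session,
                                                       coarse_lf_module):
        stim, sched = tiny_session
        lf = coarse_lf_module
        cfg = sd.SimulationConfig(seed=3, fs_eeg=500.0, coupling_gain=5.0)
        rec = sd.simulate_eeg(stim, sched, lf, lf.grid[[20, 45]], cfg)
        tr = sched.music_trials()[0]
        start = int(round(tr.onset * 500))
        n = int(round(tr.duration * 500))
        env = sd.music_envelope(
            stim.piece(tr.piece_id).waveform, 500.0, 8.0, 0.1
        )[:n]
        seg = rec.data[:, start : start + n]
        r_obs = max(abs(np.corrcoef(ch, env)[0, 1]) for ch in seg)
        rng = np.random.default_rng(0)
        null = []
        best = seg[
            np.argmax([abs(np.corrcoef(ch, env)[0, 1]) for ch in seg])
        ]
        for _ in range(200):
            shift = rng.integers(1, n)
            null.append(abs(np.corrcoef(np.roll(best, shift), env)[0, 1]))
        assert r_obs > np.quantile(null, 0.95)

    def test_off_grid_dipole_raises(self, tiny_session, coarse_lf_module):
        stim, sched = tiny_session
        cfg = sd.SimulationConfig(seed=0, fs_eeg=500.0)
        with pytest.raises(LookupError, match="not on the leadfield grid"):
            sd.simulate_eeg(stim, sched, coarse_lf_module,
                            np.array([[7.0, 7.0, 7.0]]), cfg)


@pytest.fixture(scope="module")
def schedule():
    stim = sd.generate_music(8, 2.0, 100.0, (60, 180), seed=1)
    return sd.generate_schedule(2, 6, stim, seed=2, type_mix=(2, 2, 2),
                                trial_duration_s=20.0, post_run_rest_s=12.0)


class TestSimulateBOLD:
    def test_zero_amplitude_planted_indistinguishable(self, schedule):
        from scipy import stats

        centres = np.array([[30.0, 30.0, 30.0], [-30.0, -30.0, -30.0]])
        bold = sd.simulate_bold(schedule, active_cluster_centres=centres,
                                seed=5, amplitude=0.0, noise_sd=1.0)
        tmap = fm.glm_tmap(bold.img, schedule)
        ks = stats.ks_2samp(tmap.t[bold.active_mask], tmap.t[~bold.active_mask])
        assert ks.pvalue > 0.01

    def test_noiseless_argmax_is_planted_centre(self, schedule):
        centres = np.array([[30.0, 30.0, 30.0]])
        bold = sd.simulate_bold(
            schedule, active_cluster_centres=centres, seed=5,
            amplitude=1.0, noise_sd=0.0, cluster_radius_mm=1.0,
        )
        tmap = fm.glm_tmap(bold.img, schedule)
        best = tmap.coords[np.argmax(tmap.t)]
        assert np.allclose(best, centres[0])

    def test_off_grid_centre_raises(self, schedule):
        with pytest.raises(LookupError, match="not on the grid"):
            sd.simulate_bold(schedule,
                             active_cluster_centres=np.array([[1.0, 2.0, 3.0]]),
                             seed=0)

    def test_detection_rate_matches_ols_oracle(self, schedule):
        """T statistics agree with an independent per-voxel OLS fit."""
        import statsmodels.api as sm

        centres = np.array([[30.0, 30.0, 30.0]])
        bold = sd.simulate_bold(schedule, active_cluster_centres=centres,
                                seed=6, amplitude=0.4, noise_sd=1.0)
        tmap = fm.glm_tmap(bold.img, schedule)
        X, names, _ = fm.build_design(schedule)
        data = np.asarray(bold.img.get_fdata()).reshape(len(tmap.t), -1)
        c = np.zeros(X.shape[1])
        c[0], c[1] = 1.0, -1.0
        rng = np.random.default_rng(0)
        for v in rng.choice(len(tmap.t), 25, replace=False):
            fit = sm.OLS(data[v], X).fit()
            t_oracle = fit.t_test(c).tvalue.item()
            assert tmap.t[v] == pytest.approx(t_oracle, rel=1e-8)
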