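"""Similarity measures, bootstrap/permutation significance, rank accuracy
and the tempo confound."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from musedecode import evaluation as ev


def toy_trials(rng, n=6, T=400, fs=100.0):
    """Band-limited random trials with distinct spectral content."""
    from scipy import signal

    out = []
    for i in range(n):
        x = rng.standard_normal(T)
        sos = signal.butter(4, [0.5 + 0.4 * i, 2.0 + 0.6 * i], btype="band",
                            fs=fs, output="sos")
        out.append(signal.sosfiltfilt(sos, x))
    return out


class TestSSIM:
    def test_identity(self, rng):
        img = rng.standard_normal((30, 40))
        assert ev.ssim(img, img) == pytest.approx(1.0)

    def test_symmetry(self, rng):
        a = rng.standard_normal((25, 25))
        b = rng.standard_normal((25, 25))
        assert ev.ssim(a, b) == pytest.approx(ev.ssim(b, a), abs=1e-12)

    def test_constant_shift_matches_closed_form(self):
        """Two constant images differ only in luminance; every window gives
        l = C1 / (mu_a^2 + mu_b^2 + C1) after joint normalisation to [0, 1]."""
        a = np.full((20, 20), 5.0)
        b = np.full((20, 20), 105.0)  # normalises to 0 and 1
        c1 = 0.01**2
        expected = (0.0 + c1) / (0.0 + 1.0 + c1)  # 2*mu_a*mu_b = 0
        assert ev.ssim(a, b) == pytest.approx(expected, rel=1e-10)
        assert ev.ssim(a, b) < 1.0

    def test_shape_mismatch_raises(self, rng):
        with pytest.raises(ValueError, match="shape"):
            ev.ssim(rng.standard_normal((10, 10)),
                    rng.standard_normal((10, 11)))

    @given(seed=st.integers(0, 500))
    def test_bounded(self, seed):
        r = np.random.default_rng(seed)
        v = ev.ssim(r.standard_normal((15, 15)), r.standard_normal((15, 15)))
        assert -1.0 <= v <= 1.0


class TestSimilaritySuite:
    def test_identical_reconstruction(self, rng):
        trials = toy_trials(rng)
        rep = ev.similarity_suite(trials, [t.copy() for t in trials],
                                  n_boot=200)
        assert np.allclose(rep.r_time, 1.0)
        assert np.allclose(rep.r_freq, 1.0)
        assert np.allclose(rep.ssim_tf, 1.0)
        assert rep.p_ssim == pytest.approx(1 / 201)

    def test_sign_flip(self, rng):
        trials = toy_trials(rng)
        rep = ev.similarity_suite(trials, [-t for t in trials], n_boot=200)
        assert np.allclose(rep.r_time, -1.0)
        assert np.allclose(rep.r_freq, 1.0)  # power spectrum unchanged

    def test_pearson_matches_hand_calculation(self):
        """4-sample fixture against the closed-form Pearson formula."""
        o = np.array([1.0, 2.0, 3.0, 4.0])
        r = np.array([1.0, 3.0, 2.0, 4.0])
        num = np.sum((o - o.mean()) * (r - r.mean()))
        den = np.sqrt(np.sum((o - o.mean()) ** 2) * np.sum((r - r.mean()) ** 2))
        rep = ev.similarity_suite([o, o[::-1]], [r, r[::-1]], n_boot=100)
        assert rep.r_time[0] == pytest.approx(num / den)
        assert num / den == pytest.approx(0.8)

    def test_constant_series_recorded_missing(self, rng, caplog):
        trials = toy_trials(rng, n=3)
        recon = [t.copy() for t in trials]
        recon[1] = np.zeros_like(recon[1])
        with caplog.at_level("INFO"):
            rep = ev.similarity_suite(trials, recon, n_boot=100)
        assert np.isnan(rep.r_time[1])
        assert not np.isnan(rep.mean_r_time)
        assert "excluded" in caplog.text


class TestBootstrapNull:
    def test_extreme_observation_floor_p(self):
        C = np.zeros((8, 8))
        np.fill_diagonal(C, 1.0)  # observed mean far above every null draw
        p = ev.bootstrap_null(C, n_boot=4000, seed=0)
        assert p == pytest.approx(1 / 4001)

    def test_small_n_boot_warns(self, rng, caplog):
        C = rng.standard_normal((5, 5))
        with caplog.at_level("WARNING"):
            ev.bootstrap_null(C, n_boot=50, seed=0)
        assert "coarse" in caplog.text

    def test_needs_two_trials(self):
        with pytest.raises(ValueError, match="2 trials"):
            ev.bootstrap_null(np.ones((1, 1)))


class TestRankAccuracy:
    def test_perfect_reconstruction_rank_one(self, rng):
        trials = toy_trials(rng, n=6, T=500)
        res = ev.rank_accuracy(trials, [t.copy() for t in trials],
                               piece_ids=np.arange(6))
        assert np.allclose(res.rank_acc, 1.0)
        assert res.mean_rank_acc == 1.0

    def test_three_trial_hand_enumeration(self):
        """3x3 similarity fixture against exhaustive hand counting."""
        C = np.array([
            [0.9, 0.2, 0.5],   # trial 0: beats both -> 1.0
            [0.4, 0.3, 0.6],   # trial 1: beats 0 of 2 ... 0.3 vs {0.4, 0.6} -> 0
            [0.1, 0.7, 0.7],   # trial 2: ties with col 1 -> half credit 0.5...
        ])
        # hand enumeration: row0: 0.9 > {0.2, 0.5} -> 2/2 = 1.0
        # row1: 0.3 > {0.4, 0.6}: 0 wins -> 0.0
        # row2: 0.7 vs {0.1, 0.7}: one win, one tie -> (1 + 0.5)/2 = 0.75
        acc = ev.rank_accuracy_matrix(C, piece_ids=np.arange(3))
        assert acc.tolist() == [1.0, 0.0, 0.75]

    def test_null_chance_level(self):
        """i.i.d. similarity matrices give mean rank accuracy 0.5."""
        rng = np.random.default_rng(0)
        means = [
            ev.rank_accuracy_matrix(rng.standard_normal((36, 36))).mean()
            for _ in range(300)
        ]
        assert np.mean(means) == pytest.approx(0.5, abs=0.01)

    def test_same_piece_trials_excluded_from_comparisons(self, rng):
        trials = toy_trials(rng, n=6)
        piece_ids = np.array([0, 0, 1, 1, 2, 2])
        res = ev.rank_accuracy(trials, [t.copy() for t in trials],
                               piece_ids=piece_ids)
        assert np.all(res.comparison_sizes == 4)
        res_all = ev.rank_accuracy(trials, [t.copy() for t in trials],
                                   piece_ids=piece_ids, exclusion="self_only")
        assert np.all(res_all.comparison_sizes == 5)

    def test_all_same_piece_errors(self, rng):
        trials = toy_trials(rng, n=3)
        with pytest.raises(ValueError, match="comparison set"):
            ev.rank_accuracy(trials, trials, piece_ids=np.zeros(3))

    def test_global_offset_and_scale_invariance(self, rng):
        """z-scoring and the continuous band-pass make the ranking invariant
        to a global affine transform of the reconstructions."""
        trials = toy_trials(rng, n=4)
        recon = [0.3 * t + 50.0 for t in trials]
        res = ev.rank_accuracy(trials, recon, piece_ids=np.arange(4))
        base = ev.rank_accuracy(trials, [t.copy() for t in trials],
                                piece_ids=np.arange(4))
        assert np.allclose(res.rank_acc, base.rank_acc)


class TestRankSignificance:
    def test_perfect_decoder_minimal_p(self):
        C = -np.ones((10, 10)) + 2 * np.eye(10)
        acc = ev.rank_accuracy_matrix(C)
        res = ev.RankResult(
            C=C, rank_acc=acc, mean_rank_acc=float(acc.mean()),
            piece_ids=np.arange(10), comparison_sizes=np.full(10, 9),
            exclusion="different_piece",
        )
        p = ev.rank_significance(res, n_perm=500, seed=1)
        assert p <= 2 / 501
        assert res.p_value == p

    def test_monotone_in_observed_accuracy(self, rng):
        C = rng.standard_normal((12, 12))
        acc = ev.rank_accuracy_matrix(C)
        base = dict(
            C=C, rank_acc=acc, piece_ids=np.arange(12),
            comparison_sizes=np.full(12, 11), exclusion="different_piece",
        )
        lo = ev.RankResult(mean_rank_acc=0.55, **base)
        hi = ev.RankResult(mean_rank_acc=0.85, **base)
        assert ev.rank_significance(hi, 300, seed=2) <= ev.rank_significance(
            lo, 300, seed=2
        )


class TestTempo:
    def make_metronome(self, bpm, fs=1000.0, duration=20.0, jitter_sd=0.0,
                       seed=0):
        rng = np.random.default_rng(seed)
        beat = 60.0 / bpm
        onsets = np.arange(0.0, duration, beat)
        if jitter_sd:
            onsets = np.sort(onsets + rng.normal(0, jitter_sd * beat,
                                                 len(onsets)))
            onsets = np.clip(onsets, 0, duration - 0.5)
        t_note = np.arange(int(0.3 * fs)) / fs
        w = np.zeros(int(duration * fs))
        for t0 in onsets:
            i = int(t0 * fs)
            seg = min(len(t_note), len(w) - i)
            w[i : i + seg] += np.exp(-t_note[:seg] / 0.05)
        return w, onsets

    @pytest.mark.parametrize("bpm", [60.0, 120.0])
    def test_metronome_tempo_recovered(self, bpm):
        w, _ = self.make_metronome(bpm)
        mean_bpm, (lo, hi) = ev.estimate_tempo(w, 1000.0)
        assert mean_bpm == pytest.approx(bpm, abs=1.0)
        assert lo <= mean_bpm <= hi

    def test_jittered_onsets_match_oracle(self):
        """Estimated tempo agrees with the oracle computed from the known
        onset list."""
        w, onsets = self.make_metronome(100.0, jitter_sd=0.06, seed=3)
        oracle = 60.0 / np.median(np.diff(onsets))
        mean_bpm, _ = ev.estimate_tempo(w, 1000.0)
        assert mean_bpm == pytest.approx(oracle, rel=0.02)

    def test_too_few_onsets_flagged(self, caplog):
        with caplog.at_level("WARNING"):
            mean_bpm, rng_bpm = ev.estimate_tempo(np.zeros(5000), 1000.0)
        assert np.isnan(mean_bpm)
        assert "undefined" in caplog.text

    def test_affine_relation_gives_r_one(self):
        tempos = np.array([60.0, 80, 100, 120, 140, 160])
        rep = ev.tempo_confound(tempos, 0.002 * tempos + 0.3)
        assert rep.r_tempo == pytest.approx(1.0)

    def test_hand_computed_six_point_fixture(self):
        tempos = np.array([60.0, 70, 80, 90, 100, 110])
        accs = np.array([0.5, 0.6, 0.4, 0.7, 0.55, 0.65])
        num = np.sum((tempos - tempos.mean()) * (accs - accs.mean()))
        den = np.sqrt(
            np.sum((tempos - tempos.mean()) ** 2)
            * np.sum((accs - accs.mean()) ** 2)
        )
        rep = ev.tempo_confound(tempos, accs)
        assert rep.r_tempo == pytest.approx(num / den)

    def test_independent_accs_weakly_correlated(self):
        rng = np.random.default_rng(2)
        tempos = rng.uniform(60, 180, 30)
        accs = rng.uniform(0.3, 0.7, 30)  # independent by construction
        rep = ev.tempo_confound(tempos, accs)
        assert abs(rep.r_tempo) < 0.5

    def test_zero_variance_tempos_missing(self, caplog):
        with caplog.at_level("WARNING"):
            rep = ev.tempo_confound(np.full(5, 120.0), np.linspace(0, 1, 5))
        assert np.isnan(rep.r_tempo)
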