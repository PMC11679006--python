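"""Windowing, window classes and the 8 COP features."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fogsentry import (
    EventInterval,
    EventKind,
    FootTrack,
    GaitLabel,
    TrialRecord,
    classify_window,
    count_ap_reversals,
    derive_sample_labels,
    dominant_frequency,
    extract_features,
    feature_matrix,
    make_windows,
    wavelet_approx_power,
)

FS = 100.0


class TestMakeWindows:
    @pytest.mark.parametrize("T,expected", [(3.0, 11), (1.0, 1), (2.2, 7), (60.0, 296)])
    def test_count_formula(self, T, expected):
        ws = make_windows(int(T * FS), FS)
        assert len(ws) == expected
        assert len(ws) == int(np.floor((T - 1.0) / 0.2)) + 1

    def test_short_trial_raises(self):
        with pytest.raises(ValueError):
            make_windows(90, FS)

    def test_grid_alignment(self):
        ws = make_windows(300, FS)
        assert ws[0].start == 0.0
        starts = np.array([w.start for w in ws])
        np.testing.assert_allclose(np.diff(starts), 0.2, atol=1e-12)
        assert all(w.end - w.start == pytest.approx(1.0) for w in ws)


class TestClassifyWindow:
    def test_pure_fog_is_target(self):
        assert classify_window(np.full(100, GaitLabel.FOG))

    def test_prefog_fog_mix_is_target(self):
        labels = np.r_[np.full(40, GaitLabel.PREFOG), np.full(60, GaitLabel.FOG)]
        assert classify_window(labels)

    def test_any_nonfog_sample_makes_nontarget(self):
        labels = np.full(100, GaitLabel.FOG)
        labels[57] = GaitLabel.NONFOG
        assert not classify_window(labels)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_equals_forall_predicate(self, seed):
        rng = np.random.default_rng(seed)
        labels = rng.choice([0, 1, 2], size=100, p=[0.2, 0.4, 0.4])
        assert classify_window(labels) == all(l != GaitLabel.NONFOG for l in labels)


class TestReversals:
    def test_monotone_ramp_zero(self):
        assert count_ap_reversals(np.linspace(0, 50, 100)) == 0

    def test_constant_zero(self):
        assert count_ap_reversals(np.zeros(100)) == 0

    def test_two_hz_sinusoid_four_reversals(self):
        t = np.arange(100) / FS
        x = 10.0 * np.sin(2 * np.pi * 2 * t)
        # brute-force extrema count of the noiseless sampled signal
        sign = np.sign(np.diff(x))
        sign = sign[sign != 0]
        brute = int((sign[1:] != sign[:-1]).sum())
        assert brute == 4
        assert count_ap_reversals(x, hysteresis=1.0) == 4

    def test_resets_across_invalid_runs(self):
        t = np.arange(100) / FS
        x = 10.0 * np.sin(2 * np.pi * 2 * t)
        valid = np.ones(100, bool)
        valid[40:60] = False  # cuts through one extremum pair
        assert count_ap_reversals(x, valid) <= 4

    def test_all_invalid_counts_zero(self):
        assert count_ap_reversals(np.random.default_rng(0).normal(size=100), np.zeros(100, bool)) == 0

    def test_sub_hysteresis_noise_ignored(self):
        rng = np.random.default_rng(1)
        x = np.linspace(0, 80, 100) + rng.uniform(-0.3, 0.3, 100)
        assert count_ap_reversals(x, hysteresis=1.0) == 0


class TestDominantFrequency:
    def test_pure_tone_on_bin(self):
        t = np.arange(100) / FS
        assert dominant_frequency(np.sin(2 * np.pi * 5 * t)) == 5.0

    def test_larger_component_wins(self):
        t = np.arange(100) / FS
        x = 1.0 * np.sin(2 * np.pi * 3 * t) + 2.0 * np.sin(2 * np.pi * 7 * t)
        # independent check: explicit DFT matrix argmax
        k = np.arange(1, 51)
        mags = np.abs(np.exp(-2j * np.pi * np.outer(k, np.arange(100)) / 100) @ (x - x.mean()))
        assert k[np.argmax(mags)] == 7
        assert dominant_frequency(x) == 7.0

    def test_constant_signal_ties_to_lowest_bin(self):
        assert dominant_frequency(np.full(100, 4.2)) == 1.0

    def test_dc_excluded(self):
        t = np.arange(100) / FS
        assert dominant_frequency(100.0 + 0.1 * np.sin(2 * np.pi * 6 * t)) == 6.0


class TestWaveletPower:
    def test_zero_signal(self):
        assert wavelet_approx_power(np.zeros(100)) == 0.0

    def test_quadratic_homogeneity(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=100)
        assert wavelet_approx_power(2 * x) == pytest.approx(4 * wavelet_approx_power(x), rel=1e-9)

    def test_demean_restores_offset_invariance(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=100)
        assert wavelet_approx_power(x + 1000.0) == pytest.approx(wavelet_approx_power(x), rel=1e-6)

    def test_constant_without_demean_matches_conv_oracle(self):
        from .dwt_oracle import wavedec_approx_oracle

        x = np.full(100, 3.0)
        ours = wavelet_approx_power(x, demean=False)
        approx = wavedec_approx_oracle(x, "db4", 4)
        assert ours == pytest.approx(float(np.mean(approx**2)), rel=1e-9)
        assert ours > 0


class TestExtractFeatures:
    def test_trembling_window_dominant_frequency_matches_generator(self, sim_trial):
        trial, truth = sim_trial
        windows, X, y, _ = feature_matrix(trial)
        for ev, phen in zip(trial.fog_events(), truth.phenotypes):
            if phen != "trembling":
                continue
            inside = [w.index for w in windows if w.start >= ev.start and w.end <= ev.end]
            if not inside:
                continue
            freq = 6.0  # template config; per-trial fixture uses the default
            np.testing.assert_allclose(X[inside, 4], X[inside, 5])
            assert np.all(np.abs(X[inside, 4] - freq) <= 1.0)

    def test_degenerate_foot_yields_zeros_and_flag(self):
        n = 300
        t = np.arange(n) / FS
        rng = np.random.default_rng(5)
        force_l = np.full(n, 500.0)
        force_l[:120] = 1.0  # left foot unloaded for the first window
        left = FootTrack(t, force_l, rng.normal(0, 5, n), rng.normal(0, 5, n), force_l > 50)
        right = FootTrack(t, np.full(n, 500.0), rng.normal(0, 5, n), rng.normal(0, 5, n), np.ones(n, bool))
        trial = TrialRecord("P", "T", FS, left, right, [])
        windows, X, y, degen = feature_matrix(trial)
        fv = extract_features(trial, windows[0])
        assert degen[0]
        assert fv.degenerate
        assert fv.revAP_L == fv.domML_L == fv.domAP_L == fv.wavAP_L == 0.0
        assert fv.wavAP_R > 0  # the loaded foot still produces features

    def test_offset_invariance_of_feature_vector(self, sim_trial):
        trial, _ = sim_trial
        _, X0, _, _ = feature_matrix(trial)
        shifted = TrialRecord(
            trial.participant_id,
            trial.trial_id,
            trial.fs,
            FootTrack(
                trial.left.times, trial.left.force,
                trial.left.cop_x, trial.left.cop_y + 500.0, trial.left.valid,
            ),
            trial.right,
            list(trial.events),
        )
        _, X1, _, _ = feature_matrix(shifted)
        np.testing.assert_allclose(X0, X1, rtol=1e-6, atol=1e-6)


def test_target_window_count_lower_bound():
    """An episode of duration d after >=2 s walking yields at least
    floor((d + 2 - 1)/0.2) + 1 target windows when onset sits on the grid."""
    for onset, dur in [(10.0, 3.0), (8.0, 1.2), (12.0, 0.8)]:
        T = onset + dur + 5.0
        times = np.arange(int(T * FS)) / FS
        labels = derive_sample_labels([EventInterval(onset, onset + dur, EventKind.FOG)], times)
        ws = make_windows(len(times), FS)
        n_target = sum(classify_window(labels[w.i0:w.i1]) for w in ws)
        assert n_target >= int(np.floor((dur + 2.0 - 1.0) / 0.2)) + 1
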