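"""MTD mechanics, target zones, episode outcomes and cross-validation."""

import numpy as np
import pytest

from fogsentry import (
    EventInterval,
    EventKind,
    MetricsReport,
    MtdEvent,
    MtdStatus,
    apply_no_cue,
    build_target_zones,
    classify_mtds,
    detect_mtds,
    episode_outcomes,
    id_histogram,
    lofo_crossval,
    simulate_cohort,
    window_metrics,
)


def _ends(flags):
    """Window end times for a boolean stream on the 0.2 s grid."""
    return 1.0 + 0.2 * np.arange(len(flags))


def brute_force_mtds(flags, run_length=3, no_cue=2.5):
    """O(n*k) reference: scan runs, then greedy refractory thinning."""
    ends = _ends(flags)
    cands = [
        ends[i]
        for i in range(len(flags))
        if i >= run_length - 1 and all(flags[i - j] for j in range(run_length))
    ]
    kept, last = [], -np.inf
    for t in cands:
        if t - last >= no_cue - 1e-9:
            kept.append(t)
            last = t
    return cands, kept


class TestDetectMtds:
    def test_run_of_three_fires_once_at_third_end(self):
        flags = [False, True, True, True, False]
        cands = detect_mtds(_ends(flags), flags)
        assert [c.instant for c in cands] == [pytest.approx(_ends(flags)[3])]

    def test_broken_runs_fire_nothing(self):
        flags = [True, True, False, True, True, False]
        assert detect_mtds(_ends(flags), flags) == []

    def test_run_of_five_fires_at_each_window_from_third(self):
        flags = [True] * 5
        cands = detect_mtds(_ends(flags), flags)
        np.testing.assert_allclose([c.instant for c in cands], _ends(flags)[2:])

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            flags = list(rng.random(60) < rng.uniform(0.2, 0.8))
            cands, _ = brute_force_mtds(flags)
            ours = detect_mtds(_ends(flags), flags)
            np.testing.assert_allclose([c.instant for c in ours], cands)


class TestNoCue:
    def test_close_follower_suppressed(self):
        out = apply_no_cue([MtdEvent(2.0), MtdEvent(3.5)])
        assert out[0].status is MtdStatus.CANDIDATE
        assert out[1].status is MtdStatus.SUPPRESSED_NOCUE

    def test_far_follower_kept(self):
        out = apply_no_cue([MtdEvent(2.0), MtdEvent(4.6)])
        assert all(m.status is MtdStatus.CANDIDATE for m in out)

    def test_single_candidate_kept(self):
        assert apply_no_cue([MtdEvent(1.4)])[0].status is MtdStatus.CANDIDATE

    def test_kept_mtds_always_at_least_interval_apart(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            cands = [MtdEvent(t) for t in np.sort(rng.uniform(0, 30, 40))]
            kept = [m.instant for m in apply_no_cue(cands) if m.status is MtdStatus.CANDIDATE]
            assert (np.diff(kept) >= 2.5 - 1e-9).all()


def _fog(s, e):
    return EventInterval(s, e, EventKind.FOG)


def _turn(s, e):
    return EventInterval(s, e, EventKind.TURN)


def _stand(s, e):
    return EventInterval(s, e, EventKind.STAND)


class TestTargetZones:
    def test_clean_six_second_zone(self):
        (z,) = build_target_zones([_fog(10.0, 13.0)])
        assert z.zone_start == pytest.approx(4.0)
        assert z.onset == 10.0 and z.zone_end == 13.0

    def test_turn_pushes_start_one_second_after_its_end(self):
        (z,) = build_target_zones([_fog(10.0, 13.0), _turn(5.0, 6.0)])
        assert z.zone_start == pytest.approx(7.0)

    def test_prior_fog_truncates_without_extra_delay(self):
        z = build_target_zones([_fog(2.0, 5.5), _fog(10.0, 12.0)])[1]
        assert z.zone_start == pytest.approx(5.5)

    def test_onset_near_trial_start_clips_to_zero(self):
        (z,) = build_target_zones([_fog(3.0, 6.0)])
        assert z.zone_start == 0.0

    def test_prediction_zone_never_longer_than_six_seconds(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            onset = rng.uniform(1, 40)
            events = [_fog(onset, onset + rng.uniform(0.5, 5))]
            if rng.random() < 0.7:
                s = rng.uniform(0, onset - 0.2)
                events.append(_turn(s, min(s + 2, onset - 0.1)))
            for z in build_target_zones(events):
                assert z.onset - z.zone_start <= 6.0 + 1e-9
                assert z.zone_start <= z.onset <= z.zone_end


class TestClassifyMtds:
    ZONES = build_target_zones([_fog(10.0, 13.0)])
    STANDS = [_stand(20.0, 24.0)]

    def classify(self, t):
        return classify_mtds([MtdEvent(t)], self.ZONES, self.STANDS)[0]

    def test_inside_zone_is_tp_matched(self):
        m = self.classify(8.0)
        assert m.status is MtdStatus.TP and m.matched_episode == 0

    def test_during_gait_initiation_ignored(self):
        assert self.classify(24.5).status is MtdStatus.IGNORED_STAND_OR_INIT

    def test_during_standing_ignored(self):
        assert self.classify(21.0).status is MtdStatus.IGNORED_STAND_OR_INIT

    def test_open_walking_is_fp(self):
        assert self.classify(17.0).status is MtdStatus.FP

    def test_suppressed_pass_through(self):
        m = MtdEvent(8.0, MtdStatus.SUPPRESSED_NOCUE)
        out = classify_mtds([m], self.ZONES, self.STANDS)
        assert out[0].status is MtdStatus.SUPPRESSED_NOCUE


class TestEpisodeOutcomes:
    ZONES = build_target_zones([_fog(10.0, 13.0)])

    def outcomes(self, instants):
        mtds = [MtdEvent(t, MtdStatus.TP, 0) for t in instants]
        return episode_outcomes(self.ZONES, mtds)[0]

    def test_predicted_and_detected(self):
        o = self.outcomes([9.0, 10.4])
        assert o.predicted and o.detected and o.identified
        assert o.id_delay == pytest.approx(-1.0)

    def test_detected_only(self):
        o = self.outcomes([10.6])
        assert o.detected and not o.predicted
        assert o.id_delay == pytest.approx(0.6)

    def test_unidentified(self):
        o = self.outcomes([])
        assert not o.identified and o.id_delay is None

    def test_id_sign_encodes_prediction_vs_detection(self):
        assert self.outcomes([9.5]).id_delay < 0
        assert self.outcomes([11.0]).id_delay > 0


class TestWindowMetrics:
    def test_perfect(self):
        assert window_metrics([1, 0, 1], [1, 0, 1]) == (100.0, 100.0)

    def test_all_negative_predictions(self):
        sens, spec = window_metrics([0, 0, 0, 0], [1, 1, 0, 0])
        assert sens == 0.0 and spec == 100.0

    def test_hand_confusion_matrix(self):
        sens, spec = window_metrics([1, 0, 0, 1], [1, 1, 0, 0])
        assert sens == 50.0 and spec == 50.0

    def test_absent_class_undefined(self):
        sens, spec = window_metrics([1, 0], [1, 1])
        assert spec is None and sens is not None


class TestIdHistogram:
    def test_single_bin(self):
        edges, frac = id_histogram([-0.5, -0.5, -0.5])
        k = int(np.floor((-0.5 - edges[0])))
        assert frac[k] == 1.0

    def test_sums_to_one(self):
        rng = np.random.default_rng(3)
        _, frac = id_histogram(list(rng.uniform(-6, 8, 100)))
        assert frac.sum() == pytest.approx(1.0)

    def test_hand_binned_example(self):
        edges, frac = id_histogram([-1.2, 0.3, 0.4])
        assert edges[0] == -6.0
        bin_of = lambda v: int(np.floor(v - edges[0]))
        assert frac[bin_of(-1.2)] == pytest.approx(1 / 3)
        assert frac[bin_of(0.3)] == pytest.approx(2 / 3)

    def test_no_identifications_raises(self):
        with pytest.raises(ValueError):
            id_histogram([None, None])


class TestMetricsReportInvariant:
    def test_published_rows_satisfy_inequality(self):
        from fogsentry.reference import load_performance_table

        for _, row in load_performance_table().iterrows():
            ident, pred, det = (
                row["fog_identified_pct"],
                row["fog_predicted_pct"],
                row["fog_detected_pct"],
            )
            assert max(pred, det) <= ident + 1e-9
            assert ident <= pred + det + 1e-9

    def test_violating_report_rejected(self):
        with pytest.raises(AssertionError):
            MetricsReport(
                sensitivity=50.0, specificity=50.0,
                pct_identified=10.0, pct_predicted=40.0, pct_detected=5.0,
                mean_id=0.0, fp_rate=0.0, n_windows=10, n_episodes=5,
            )


class TestLofoCrossval:
    def test_fold_structure(self, small_cohort):
        ds, _ = small_cohort
        folds, report = lofo_crossval(ds, seed=5)
        assert len(folds) == len(ds.freezers())
        held = {f.held_out for f in folds}
        assert held == {p.id for p in ds.freezers()}
        # non-freezers never appear as held-out participants
        assert all(ds.get(h).froze for h in held)
        assert report.n_windows == sum(len(t.truth) for f in folds for t in f.trials)

    def test_report_invariant_holds_on_live_run(self, small_cohort):
        ds, _ = small_cohort
        _, report = lofo_crossval(ds, seed=5)
        assert max(report.pct_predicted, report.pct_detected) <= report.pct_identified + 1e-9
        assert report.pct_identified <= report.pct_predicted + report.pct_detected + 1e-9

    def test_fewer_than_two_freezers_raises(self):
        ds, _ = simulate_cohort(0, 2, 1, seed=0)
        with pytest.raises(ValueError, match="freezer"):
            lofo_crossval(ds)

    def test_determinism(self, small_cohort):
        ds, _ = small_cohort
        _, a = lofo_crossval(ds, seed=5)
        _, b = lofo_crossval(ds, seed=5)
        assert a.to_dict() == b.to_dict()
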