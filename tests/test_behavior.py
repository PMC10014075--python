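"""Tail-flick detection, trial assignment, Poisson correction, typing, fins."""

import numpy as np
import pandas as pd
import pytest

import loomhab as lh
from loomhab.behavior import TailTrace


def make_trace(deflection, fps=120.0):
    return TailTrace(deflection_mm=np.asarray(deflection, dtype=float), fps=fps)


def half_sine(amp, duration_s, fps, t0_s, total_s):
    x = np.zeros(int(round(total_s * fps)))
    n = int(round(duration_s * fps))
    i0 = int(round(t0_s * fps))
    x[i0 : i0 + n] = amp * np.sin(np.linspace(0, np.pi, n))
    return x


class TestTailDeflection:
    def setup_method(self):
        self.mid_pt = np.array([0.0, 50.0])
        self.mid_dir = np.array([1.0, 0.0])   # head axis along +x; +y is leftward

    def test_points_on_midline_give_zero(self):
        pts = np.zeros((5, 10, 2))
        pts[..., 0] = np.arange(10)
        pts[..., 1] = 50.0
        tr = lh.tail_deflection(pts, self.mid_pt, self.mid_dir, px_per_mm=10.0, fps=100.0)
        assert np.allclose(tr.deflection_mm, 0.0)

    def test_uniform_offset_is_reported_verbatim(self):
        pts = np.zeros((3, 10, 2))
        pts[..., 0] = np.arange(10)
        pts[..., 1] = 60.0    # +10 px = +1 mm at 10 px/mm
        tr = lh.tail_deflection(pts, self.mid_pt, self.mid_dir, px_per_mm=10.0, fps=100.0)
        assert np.allclose(tr.deflection_mm, 1.0)

    def test_curved_tail_mean_of_sampled_offsets(self):
        # quadratic offset, 2 mm at the tip
        s = np.linspace(0, 1, 10)
        offsets_mm = 2.0 * s**2
        pts = np.zeros((4, 10, 2))
        pts[..., 0] = np.arange(10)
        pts[..., 1] = 50.0 + offsets_mm * 10.0
        tr = lh.tail_deflection(pts, self.mid_pt, self.mid_dir, px_per_mm=10.0, fps=100.0)
        assert np.allclose(tr.deflection_mm, offsets_mm.mean())

    def test_short_gap_interpolated_long_gap_rejected(self):
        pts = np.zeros((8, 10, 2))
        pts[..., 1] = 50.0
        pts[3, 0, 1] = np.nan
        tr = lh.tail_deflection(pts, self.mid_pt, self.mid_dir, px_per_mm=10.0, fps=100.0)
        assert np.all(np.isfinite(tr.deflection_mm))
        pts[2:7, 0, 1] = np.nan
        with pytest.raises(ValueError, match="gap"):
            lh.tail_deflection(pts, self.mid_pt, self.mid_dir, px_per_mm=10.0, fps=100.0)


class TestDetectFlicks:
    def test_flat_trace_has_no_events(self):
        assert lh.detect_flicks(make_trace(np.zeros(2400))) == []

    def test_single_bend_onset_at_analytic_crossing(self):
        # half-sine, amplitude -1 mm, 0.3 s wide, centered at 2.0 s
        fps, d = 1000.0, 0.3
        x = half_sine(-1.0, d, fps, 2.0 - d / 2, 4.0)
        events = lh.detect_flicks(make_trace(x, fps), smooth_s=0.0)
        assert len(events) == 1
        ev = events[0]
        assert ev.peak_s == pytest.approx(2.0, abs=2 / fps)
        assert ev.peak_amp_mm == pytest.approx(-1.0, abs=1e-3)
        t_cross = (2.0 - d / 2) + (d / np.pi) * np.arcsin(0.2)
        assert ev.onset_s == pytest.approx(t_cross, abs=2 / fps)
        assert ev.onset_s < ev.peak_s

    def test_subthreshold_bend_ignored(self):
        x = half_sine(0.3, 0.3, 120.0, 1.0, 3.0)
        assert lh.detect_flicks(make_trace(x)) == []

    def test_mirror_symmetry(self):
        rng = np.random.default_rng(0)
        x = np.zeros(1200)
        for t0, amp in ((1.0, 0.8), (4.0, -1.2), (7.0, 0.6)):
            x += half_sine(amp, 0.3, 120.0, t0, 10.0)
        x += rng.normal(0, 0.02, x.size)
        ev_pos = lh.detect_flicks(make_trace(x))
        ev_neg = lh.detect_flicks(make_trace(-x))
        assert len(ev_pos) == len(ev_neg) == 3
        for a, b in zip(ev_pos, ev_neg):
            assert a.peak_s == b.peak_s
            assert a.peak_amp_mm == pytest.approx(-b.peak_amp_mm)

    def test_counterbend_recorded(self):
        fps = 120.0
        x = half_sine(-1.0, 0.3, fps, 1.0, 4.0) + half_sine(0.5, 0.15, fps, 1.3, 4.0)
        events = lh.detect_flicks(make_trace(x, fps))
        assert len(events) == 1
        assert events[0].counter_peak_amp_mm == pytest.approx(0.5, abs=0.05)

    def test_pixel_fallback_warns(self):
        x = half_sine(25.0, 0.3, 120.0, 1.0, 3.0)   # 25 px peak
        tr = TailTrace(deflection_mm=x, fps=120.0, units="px")
        with pytest.warns(UserWarning, match="pixels"):
            events = lh.detect_flicks(tr)
        assert len(events) == 1


class TestAssignResponses:
    @pytest.fixture
    def train(self):
        return lh.behavior_train(n_trials=3, isi_s=10.0, start_s=0.0)

    def ev(self, t):
        return lh.FlickEvent(onset_s=t, peak_s=t + 0.05, peak_amp_mm=-1.0)

    def test_response_before_collision_counts(self, train):
        coll = train.collision_times_s()[0]
        table = lh.assign_responses([self.ev(coll - 1.3)], train, mode="main")
        assert bool(table.loc[0, "responded"])
        assert table.loc[0, "response_time_s"] == pytest.approx(-1.3)
        assert table.loc[0, "peak_amp_mm"] == -1.0

    def test_event_before_five_degrees_excluded_early(self, train):
        e = self.ev(train.onsets_s[0] + 0.2)   # theta still ~4-5 deg
        table = lh.assign_responses([e], train, mode="main")
        assert not table["responded"].any()
        assert e.provenance == "excluded_early"

    def test_event_late_after_collision_excluded(self, train):
        coll = train.collision_times_s()[1]
        e = self.ev(coll + 1.5)
        table = lh.assign_responses([e], train, mode="main")
        assert not table["responded"].any()
        assert e.provenance == "excluded_late"

    def test_first_encounter_mode_admits_later_events(self, train):
        coll = train.collision_times_s()[0]
        e = self.ev(coll + 1.5)
        table = lh.assign_responses([e], train, mode="first_encounter")
        assert bool(table.loc[0, "responded"])
        assert e.provenance == "evoked"

    def test_event_between_trials_is_spontaneous(self, train):
        e = self.ev(train.onsets_s[0] + train.params.duration_s + 2.0)
        lh.assign_responses([e], train, mode="main")
        assert e.provenance == "spontaneous"

    def test_overlapping_windows_rejected(self):
        p = lh.LoomingParams(l_over_v=0.240, theta_init=4.0, theta_final=140.0, hold_s=0.0)
        train = lh.StimulusTrain(params=p, n_trials=3, isi_s=0.5)
        with pytest.raises(ValueError, match="overlap"):
            lh.assign_responses([], train, mode="main")

    def test_amplitude_accounting_identity(self, train):
        # mean over all trials == response rate x mean responded amplitude
        colls = train.collision_times_s()
        events = [self.ev(colls[0] - 1.0), self.ev(colls[2] - 0.5)]
        events[1].peak_amp_mm = -2.0
        table = lh.assign_responses(events, train, mode="main")
        rate = table["responded"].mean()
        resp_mean = table.loc[table["responded"], "peak_amp_mm"].mean()
        assert table["peak_amp_mm"].mean() == pytest.approx(rate * resp_mean)


class TestSpontaneousRate:
    def test_direct_counts(self):
        assert lh.spontaneous_rate([], [(0.0, 100.0)]) == 0.0
        evs = [lh.FlickEvent(onset_s=t, peak_s=t, peak_amp_mm=1.0) for t in (1, 10, 60, 140)]
        assert lh.spontaneous_rate(evs, [(0.0, 150.0)]) == pytest.approx(4 / 150)

    def test_zero_free_time_rejected(self):
        with pytest.raises(ValueError):
            lh.spontaneous_rate([], [])

    def test_poisson_rate_recovery(self):
        rng = np.random.default_rng(42)
        lam, T = 0.0266, 10000.0
        times = np.sort(rng.uniform(0, T, rng.poisson(lam * T)))
        evs = [lh.FlickEvent(onset_s=float(t), peak_s=float(t), peak_amp_mm=1.0)
               for t in times]
        est = lh.spontaneous_rate(evs, [(0.0, T)])
        se = np.sqrt(lam / T)
        assert abs(est - lam) < 3 * se


class TestCorrectedProbability:
    def test_identity_at_zero_rate(self):
        assert lh.corrected_probability(0.42, 0.0, 10.0) == 0.42

    def test_closed_form(self):
        expected = 0.6 - (1 - np.exp(-0.0266 * 10.0))
        assert lh.corrected_probability(0.6, 0.0266, 10.0) == pytest.approx(expected)
        assert expected == pytest.approx(0.3664, abs=2e-3)

    def test_clipped_at_zero(self):
        assert lh.corrected_probability(0.1, 0.1, 30.0) == 0.0

    def test_monotone_in_rate_and_window(self):
        rates = np.linspace(0, 0.2, 30)
        vals = [lh.corrected_probability(0.7, r, 10.0) for r in rates]
        assert np.all(np.diff(vals) <= 1e-12)
        windows = np.linspace(1.0, 60.0, 30)
        vals_w = [lh.corrected_probability(0.7, 0.02, w) for w in windows]
        assert np.all(np.diff(vals_w) <= 1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            lh.corrected_probability(0.5, -0.1, 10.0)
        with pytest.raises(ValueError):
            lh.corrected_probability(1.5, 0.1, 10.0)


class TestHabituationCurve:
    def test_recovers_planted_time_constant(self):
        # cohort drawn from p_k = exp(-k*ISI/60); tau recovered within 15%
        rng = np.random.default_rng(7)
        train = lh.behavior_train(n_trials=10, isi_s=10.0)
        t = np.arange(10) * 10.0
        p = 1.0 * np.exp(-t / 60.0)
        R = rng.random((200, 10)) < p
        curve = lh.habituation_curve(R, train, rate_hz=0.0, window_s=6.5, seed=0)
        assert curve.fit_ok
        assert curve.tau_s == pytest.approx(60.0, rel=0.15)
        assert curve.a == pytest.approx(1.0, rel=0.1)

    def test_constant_probability_flagged(self):
        train = lh.behavior_train(n_trials=8, isi_s=10.0)
        R = np.ones((20, 8), dtype=bool)
        curve = lh.habituation_curve(R, train, rate_hz=0.0, window_s=6.5, seed=0)
        assert not curve.fit_ok

    def test_all_zero_skips_fit(self):
        train = lh.behavior_train(n_trials=8, isi_s=10.0)
        curve = lh.habituation_curve(np.zeros((5, 8)), train, 0.0, 6.5, seed=0)
        assert not curve.fit_ok and np.isnan(curve.tau_s)

    def test_single_trial_rejected(self):
        train = lh.behavior_train(n_trials=1, isi_s=10.0)
        with pytest.raises(ValueError):
            lh.habituation_curve(np.ones((5, 1)), train, 0.0, 6.5)

    def test_bootstrap_band_brackets_point_estimate(self):
        rng = np.random.default_rng(1)
        train = lh.behavior_train(n_trials=6, isi_s=10.0)
        R = rng.random((40, 6)) < 0.5
        curve = lh.habituation_curve(R, train, 0.01, 6.5, n_boot=200, seed=3)
        assert np.all(curve.band_lo <= curve.p_corr + 1e-9)
        assert np.all(curve.band_hi >= curve.p_corr - 1e-9)


class TestResponseTypes:
    def test_two_separated_blobs_fully_recovered(self):
        rng = np.random.default_rng(0)
        a = rng.normal([0.0, 5.0, -1.0, 2.0], 0.1, (30, 4))
        b = rng.normal([1.0, 1.0, -4.0, 0.3], 0.1, (30, 4))
        X = np.vstack([a, b])
        labels = lh.classify_response_types(X, k=2, seed=0)
        assert len(np.unique(labels[:30])) == 1 and len(np.unique(labels[30:])) == 1
        assert labels[0] != labels[-1]
        # cluster 0 has the larger mean |positive peak| (column 1)
        assert labels[0] == 0

    def test_five_archetypes_recovered(self):
        # bend+counterbend / single bend / small flicks / slow bend / late flick
        means = np.array([
            [-1.0, 1.2, -0.8, 0.67],
            [-1.0, 1.4, -0.1, 14.0],
            [-0.5, 0.45, -0.3, 1.5],
            [0.5, 0.9, -0.05, 18.0],
            [1.5, 0.5, -0.5, 1.0],
        ])
        rng = np.random.default_rng(5)
        X = np.vstack([rng.normal(m, 0.08, (40, 4)) for m in means])
        truth = np.repeat(np.arange(5), 40)
        labels = lh.classify_response_types(X, k=5, seed=1)
        # map clusters to archetypes by majority vote
        correct = 0
        for c in range(5):
            votes = labels[truth == c]
            correct += (votes == np.bincount(votes).argmax()).sum()
        assert correct / len(truth) >= 0.90

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            lh.classify_response_types(np.zeros((3, 4)), k=5, seed=0)

    def test_identical_rows_single_label(self):
        X = np.ones((10, 4))
        labels = lh.classify_response_types(X, k=3, seed=0)
        assert len(np.unique(labels)) == 1


class TestDirectionStats:
    def table(self, amps):
        return pd.DataFrame({"responded": [a is not None for a in amps],
                             "peak_amp_mm": [a if a is not None else 0.0 for a in amps]})

    def test_all_away(self):
        assert lh.direction_stats(self.table([-1.0, -0.5, -2.0])) == 1.0

    def test_three_of_four_away(self):
        assert lh.direction_stats(self.table([-1.0, -0.5, -2.0, 1.0])) == 0.75

    def test_no_responses_is_nan(self):
        assert np.isnan(lh.direction_stats(self.table([None, None])))


class TestFinMotion:
    def test_static_video_no_beats(self):
        stack = np.full((100, 64, 64), 10.0)
        fm = lh.fin_motion(stack, (5, 20, 5, 20), (44, 59, 5, 20), fps=50.0)
        assert np.allclose(fm.trace, 0.0)
        assert len(fm.beat_times_s) == 0

    def test_flicker_frequency_recovered_and_tuck_time(self):
        cfg = lh.VideoSimConfig(fin_freq_hz=2.0, duration_s=8.0, fin_stop_s=5.0)
        stack, truth = lh.simulate_tail_video(cfg, seed=3)
        from loomhab.synthetic import fin_windows
        w1, w2 = fin_windows(cfg)
        fm = lh.fin_motion(stack, w1, w2, fps=cfg.fps, reference_event_s=6.0)
        assert fm.beat_freq_hz == pytest.approx(2.0, abs=0.15)
        assert fm.tuck_time_s == pytest.approx(5.0, abs=0.6)

    def test_empty_window_rejected(self):
        stack = np.zeros((10, 32, 32))
        with pytest.raises(ValueError):
            lh.fin_motion(stack, (5, 5, 0, 10), (20, 30, 0, 10), fps=50.0)
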