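"""Exponential amplitude dynamics, rate thresholds and classification."""

import numpy as np
import pandas as pd
import pytest

import loomhab as lh
from loomhab.dynamics import PeakSeries


def series(t, y, responded=None):
    if responded is None:
        responded = np.ones(len(t), dtype=bool)
    return PeakSeries(t_s=np.asarray(t, float), peak=np.asarray(y, float),
                      responded=np.asarray(responded, bool))


class TestExtractPeakSeries:
    @pytest.fixture
    def train(self):
        return lh.dynamics_train(n_trials=5, isi_s=40.0)

    def build_trace(self, train, amps, fs=1.0, noise=None, seed=0):
        from loomhab.tuning import regressor_segment
        geom = lh.ScreenGeometry(width_px=128, height_px=128, px_per_degree=1.0)
        w = int(round((train.params.duration_s + 17.5) * fs))
        wf = regressor_segment(train.params, geom, 3.5, fs, w)
        n = int(round((train.onsets_s[-1] + train.params.duration_s + 40.0) * fs))
        trace = np.zeros(n)
        for onset, A in zip(train.onsets_s, amps):
            i0 = int(round(onset * fs))
            seg = wf[: n - i0]
            trace[i0 : i0 + len(seg)] += A * seg
        if noise:
            trace += np.random.default_rng(seed).normal(0, noise, n)
        return trace

    def test_noiseless_peaks_match_construction(self, train):
        amps = [1.0, 0.7, 0.5, 0.35, 0.25]
        trace = self.build_trace(train, amps)
        ps = lh.extract_peak_series(trace, train, fs=1.0)
        assert np.allclose(ps.peak, amps, rtol=1e-6)
        assert ps.n_responded == 0 or ps.responded.all()  # zero noise: sd == 0

    def test_flat_after_third_trial_counts_three(self, train):
        trace = self.build_trace(train, [1.0, 1.0, 1.0, 0.0, 0.0], noise=0.01)
        ps = lh.extract_peak_series(trace, train, fs=1.0, criterion_sd=5.0)
        assert ps.n_responded == 3
        assert list(ps.responded[:3]) == [True, True, True]

    def test_responded_flags_match_independent_threshold_oracle(self, train):
        trace = self.build_trace(train, [1.0, 0.2, 0.6, 0.05, 0.4], noise=0.05, seed=9)
        fs, nb, crit = 1.0, 5, 2.0
        ps = lh.extract_peak_series(trace, train, fs=fs, baseline_s=5.0, criterion_sd=crit)
        # oracle: recompute with plain loops
        onsets = np.round(np.asarray(train.onsets_s) * fs).astype(int)
        w = int(round(min(train.params.duration_s + 10.0,
                          train.params.duration_s + train.isi_s) * fs))
        base_all = np.concatenate([trace[f - nb: f] for f in onsets if f > 0])
        sd = base_all.std()
        for k, f0 in enumerate(onsets):
            base = trace[max(0, f0 - nb): f0].mean() if f0 > 0 else 0.0
            peak = (trace[f0 : f0 + w] - base).max()
            assert ps.peak[k] == pytest.approx(peak)
            assert ps.responded[k] == (peak > crit * sd)

    def test_overlapping_windows_rejected(self, train):
        trace = self.build_trace(train, [1.0] * 5)
        with pytest.raises(ValueError, match="window"):
            lh.extract_peak_series(trace, train, fs=1.0,
                                   response_window_s=train.params.duration_s + 60.0)


class TestFitExponential:
    def test_constant_peaks_give_zero_rate(self):
        t = np.arange(10) * 40.0
        fit = lh.fit_exponential(series(t, np.full(10, 0.8)))
        assert abs(fit.inv_tau) < 1e-8

    def test_noiseless_parameters_recovered_exactly(self):
        t = np.arange(10) * 40.0
        y = 1.0 * np.exp(-0.01 * t) + 0.2
        fit = lh.fit_exponential(series(t, y))
        assert fit.a == pytest.approx(1.0, rel=1e-6)
        assert fit.inv_tau == pytest.approx(-0.01, rel=1e-6)
        assert fit.c == pytest.approx(0.2, rel=1e-6)

    def test_growing_series_recovered(self):
        t = np.arange(10) * 40.0
        y = 0.5 * np.exp(0.004 * t) + 0.1
        fit = lh.fit_exponential(series(t, y))
        assert fit.inv_tau == pytest.approx(0.004, rel=1e-4)

    def test_noisy_rate_within_tolerance_in_most_replicates(self):
        rng = np.random.default_rng(0)
        t = np.arange(10) * 40.0
        y0 = 1.0 * np.exp(-0.01 * t) + 0.2
        hits = sum(
            abs(lh.fit_exponential(series(t, y0 + rng.normal(0, 0.05, 10))).inv_tau
                + 0.01) <= 0.0025
            for _ in range(500))
        assert hits / 500 >= 0.90

    def test_scale_equivariance(self):
        rng = np.random.default_rng(4)
        t = np.arange(10) * 40.0
        y = 1.0 * np.exp(-0.006 * t) + 0.3 + rng.normal(0, 0.02, 10)
        f1 = lh.fit_exponential(series(t, y))
        s = 3.7
        f2 = lh.fit_exponential(series(t, s * y))
        assert f2.inv_tau == pytest.approx(f1.inv_tau, abs=1e-8)
        assert f2.a == pytest.approx(s * f1.a, rel=1e-6)
        assert f2.c == pytest.approx(s * f1.c, rel=1e-6)

    def test_too_few_responses_excluded(self):
        t = np.arange(5) * 40.0
        fit = lh.fit_exponential(series(t, np.ones(5), [True, True, False, False, False]))
        assert fit is None


class TestWellFitRule:
    def test_ci_bound_is_ten_times_largest_rate(self):
        t = np.arange(10) * 40.0
        fits = [lh.fit_exponential(series(t, 1.0 * np.exp(k * t) + 0.1))
                for k in (-0.01, -0.005, 0.002)]
        bound = lh.flag_well_fit(fits)
        assert bound == pytest.approx(10 * 0.01, rel=1e-3)
        assert all(f.well_fit for f in fits)

    def test_unconstrained_fit_flagged_ill(self):
        t = np.arange(10) * 40.0
        good = lh.fit_exponential(series(t, np.exp(-0.01 * t) + 0.1))
        bad = lh.fit_exponential(series(t, np.exp(-0.01 * t) + 0.1))
        bad.ci_inv_tau = (-1.0, 1.0)
        lh.flag_well_fit([good, bad])
        assert good.well_fit and not bad.well_fit


class TestRateThresholds:
    def test_two_component_mixture_recovered(self):
        rng = np.random.default_rng(5)
        x = np.concatenate([rng.normal(0, 1e-5, 3000), rng.normal(-7.5e-3, 1e-3, 2000)])
        thr = lh.rate_thresholds(x)
        mu1, s1, _ = thr.near_zero
        mu2, _, _ = thr.second
        assert mu2 == pytest.approx(-7.5e-3, rel=0.05)
        assert abs(mu1) < 0.05 * abs(mu2)
        # thresholds are the near-zero mean +/- FWHM/2, hence symmetric about it
        half = np.sqrt(2 * np.log(2)) * s1
        assert thr.pos_thr == pytest.approx(mu1 + half)
        assert thr.neg_thr == pytest.approx(mu1 - half)
        assert thr.neg_thr < 0 < thr.pos_thr

    def test_single_symmetric_gaussian_gives_symmetric_thresholds(self):
        rng = np.random.default_rng(6)
        thr = lh.rate_thresholds(rng.normal(0, 1e-3, 3000))
        assert thr.pos_thr == pytest.approx(-thr.neg_thr,
                                            abs=0.05 * (thr.pos_thr - thr.neg_thr))

    def test_override_passes_published_constants_through(self):
        thr = lh.rate_thresholds(np.zeros(0), override=(4.13e-5, -1.17e-5))
        assert thr.pos_thr == 4.13e-5
        assert thr.neg_thr == -1.17e-5

    def test_bin_width_halving_stability(self):
        # component widths must be resolvable at both binnings for the spread
        # to be bin-stable (sub-bin peaks are floored at the bin width)
        rng = np.random.default_rng(7)
        x = np.concatenate([rng.normal(0, 1.2e-3, 3000), rng.normal(-7.5e-3, 1e-3, 2000)])
        h = float(np.diff(np.histogram_bin_edges(x, bins="fd"))[0])
        n1 = int(np.ptp(x) / h)
        thr1 = lh.rate_thresholds(x, bins=n1)
        thr2 = lh.rate_thresholds(x, bins=2 * n1)
        spread1 = thr1.pos_thr - thr1.neg_thr
        spread2 = thr2.pos_thr - thr2.neg_thr
        assert spread2 == pytest.approx(spread1, rel=0.25)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            lh.rate_thresholds(np.zeros(5))


class TestClassifyDynamics:
    @pytest.fixture
    def paper_thr(self):
        return lh.rate_thresholds(np.zeros(0), override=(4.13e-5, -1.17e-5))

    def test_zero_rate_is_stable(self, paper_thr):
        assert lh.classify_dynamics(0.0, paper_thr) == "stable"

    def test_published_threshold_boundaries(self, paper_thr):
        assert lh.classify_dynamics(1.0e-4, paper_thr) == "potentiating"
        assert lh.classify_dynamics(-1.0e-4, paper_thr) == "depressing"
        assert lh.classify_dynamics(2.0e-5, paper_thr) == "stable"

    def test_ill_fit_uses_sign_and_is_never_stable(self, paper_thr):
        assert lh.classify_dynamics(-1e-6, paper_thr, well_fit=False) == "depressing"
        assert lh.classify_dynamics(1e-6, paper_thr, well_fit=False) == "potentiating"

    def test_population_labels_partition(self):
        rng = np.random.default_rng(8)
        t = np.arange(10) * 40.0
        fits = []
        for k in np.concatenate([rng.normal(-7.5e-3, 1e-3, 40),
                                 rng.normal(0, 1e-5, 30), rng.normal(5e-3, 1e-3, 30)]):
            y = np.exp(k * t) + 0.1 + rng.normal(0, 0.02, 10)
            fits.append(lh.fit_exponential(series(t, y)))
        table, thr = lh.classify_population(fits)
        assert len(table) == 100
        counts = table["dyn_class"].value_counts()
        assert counts.sum() == 100
        assert set(counts.index) <= {"depressing", "potentiating", "stable"}


class TestCovertDepressionContrast:
    def make_peaks(self, rng, t1, t10, t11, cond, n=50, sd=0.1):
        rows = []
        for trial, mu in ((1, t1), (10, t10), (11, t11)):
            for v in rng.normal(mu, sd, n):
                rows.append({"condition": cond, "trial": trial, "peak": v})
        return pd.DataFrame(rows)

    def test_identical_groups_give_p_one(self):
        df = pd.DataFrame({"condition": ["wait"] * 9,
                           "trial": [1, 1, 1, 10, 10, 10, 11, 11, 11],
                           "peak": [1.0] * 9})
        out = lh.covert_depression_contrast(df)
        p = out.loc[out["contrast"] == "trial1_vs_trial10", "p_value"].iloc[0]
        assert p == 1.0

    def test_habituation_contrast_detected_with_power(self):
        # trial-10 peaks shifted down by 2 SD: p < 0.01 in nearly all replicates
        rng = np.random.default_rng(9)
        hits = 0
        for _ in range(100):
            df = self.make_peaks(rng, 1.0, 0.8, 0.95, "wait", n=50, sd=0.1)
            out = lh.covert_depression_contrast(df)
            p = out.loc[out["contrast"] == "trial1_vs_trial10", "p_value"].iloc[0]
            hits += p < 0.01
        assert hits >= 95

    def test_recovery_versus_suppression_contrast(self):
        rng = np.random.default_rng(10)
        wait = self.make_peaks(rng, 1.0, 0.4, 0.9, "wait")     # recovers to 90%
        dim = self.make_peaks(rng, 1.0, 0.4, 0.4, "dimming")   # stays suppressed
        out = lh.covert_depression_contrast(pd.concat([wait, dim]))
        p = out.loc[out["contrast"] == "trial11_across_conditions", "p_value"].iloc[0]
        assert p < 0.01
        med = out[(out["condition"] == "dimming") & (out["trial"] == 11)]["median"].iloc[0]
        assert med < 0.6

    def test_missing_trial_rejected(self):
        df = pd.DataFrame({"condition": ["wait"] * 4, "trial": [1, 1, 10, 10],
                           "peak": [1.0, 0.9, 0.5, 0.6]})
        with pytest.raises(ValueError, match="missing"):
            lh.covert_depression_contrast(df)
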