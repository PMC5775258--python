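"""Fura-2 ratio processing, responder classification, group statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nociscreen import caimaging
from nociscreen.caimaging import (
    CalibrationParams,
    StimApplication,
    StimulusSchedule,
    amplitude_fold,
    analyze_traces,
    calibrate_ca,
    classify_responders,
    compute_ratio,
    flag_desensitized,
    group_compare,
    normalize_baseline,
    percent_responders,
    responder_threshold,
)
from nociscreen.synthetic import gen_traces


def times(n, dt=2.0):
    return np.arange(n) * dt


class TestRatio:
    def test_elementwise(self):
        assert compute_ratio([2, 4], [1, 2]).tolist() == [2.0, 2.0]

    def test_identity_channels_give_ones(self):
        f = np.linspace(1, 5, 10)
        assert compute_ratio(f, f) == pytest.approx(np.ones(10))

    def test_matches_elementwise_oracle(self):
        rng = np.random.default_rng(2)
        a, b = rng.uniform(1, 5, 50), rng.uniform(1, 5, 50)
        assert compute_ratio(a, b) == pytest.approx(a / b)

    def test_zero_f380_names_index(self):
        with pytest.raises(ValueError, match="index 1"):
            compute_ratio([1.0, 1.0], [1.0, 0.0])


class TestBaselineNormalization:
    def test_constant_trace_all_ones(self):
        t = times(20)
        out = normalize_baseline(np.full(20, 0.7), t, stim_onset=20.0)
        assert out == pytest.approx(np.ones(20))

    def test_fold_relative_to_baseline(self):
        t = times(10)
        trace = np.array([0.5] * 5 + [1.0] * 5)
        out = normalize_baseline(trace, t, stim_onset=10.0)
        assert out[-1] == pytest.approx(2.0)

    def test_pre_onset_window_mean_is_exactly_one(self):
        rng = np.random.default_rng(4)
        trace = rng.uniform(0.5, 2.0, 60)
        t = times(60)
        out = normalize_baseline(trace, t, stim_onset=40.0)
        pre = np.nonzero(t < 40.0)[0][-5:]
        assert out[pre].mean() == pytest.approx(1.0, abs=1e-12)

    def test_invariant_to_channel_scaling(self):
        rng = np.random.default_rng(6)
        f340 = rng.uniform(1, 3, 40)
        f380 = rng.uniform(1, 3, 40)
        t = times(40)
        base = normalize_baseline(compute_ratio(f340, f380), t, 30.0)
        scaled = normalize_baseline(compute_ratio(3.7 * f340, 3.7 * f380), t, 30.0)
        assert scaled == pytest.approx(base)

    def test_too_few_pre_stimulus_samples(self):
        with pytest.raises(ValueError, match="pre-stimulus"):
            normalize_baseline(np.ones(10), times(10), stim_onset=6.0)


class TestCalibration:
    PARAMS = CalibrationParams(rmin=0.3, rmax=3.0, kd=224.0, beta=2.0)

    def test_rmin_maps_to_zero(self):
        assert calibrate_ca(0.3, self.PARAMS) == pytest.approx(0.0)

    def test_midpoint_gives_kd_when_beta_one(self):
        p = CalibrationParams(rmin=0.5, rmax=2.5, kd=224.0, beta=1.0)
        assert calibrate_ca(1.5, p) == pytest.approx(224.0)

    def test_algebraic_inverse_roundtrip(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            r = rng.uniform(0.3, 2.99)
            ca = calibrate_ca(r, self.PARAMS)
            # invert Ca = Kd*beta*(R-Rmin)/(Rmax-R)
            k = ca / (self.PARAMS.kd * self.PARAMS.beta)
            r_back = (self.PARAMS.rmin + k * self.PARAMS.rmax) / (1 + k)
            assert r_back == pytest.approx(r)

    def test_strictly_increasing(self):
        rs = np.linspace(0.3, 2.9, 50)
        cas = [calibrate_ca(r, self.PARAMS) for r in rs]
        assert np.all(np.diff(cas) > 0)

    def test_saturation_raises(self):
        with pytest.raises(ValueError, match="saturated"):
            calibrate_ca(3.0, self.PARAMS)


class TestAmplitude:
    WINDOW = StimApplication("AITC_low", 60.0, 90.0, 240.0)

    def test_flat_trace(self):
        t = times(130)
        assert amplitude_fold(np.ones(130), t, self.WINDOW) == 1.0

    def test_peak_in_window(self):
        t = times(130)
        trace = np.ones(130)
        trace[40] = 1.59  # t=80 s, inside the window
        trace[10] = 9.0  # outside the window, ignored
        assert amplitude_fold(trace, t, self.WINDOW) == pytest.approx(1.59)

    def test_matches_windowed_max_oracle(self):
        rng = np.random.default_rng(10)
        t = times(200)
        trace = rng.uniform(0.8, 2.0, 200)
        mask = (t >= 60.0) & (t <= 240.0)
        assert amplitude_fold(trace, t, self.WINDOW) == trace[mask].max()

    def test_empty_window_raises(self):
        with pytest.raises(ValueError, match="no samples"):
            amplitude_fold(np.ones(5), times(5), self.WINDOW)


class TestResponderThreshold:
    def test_mean_1_sd_005_gives_115(self):
        # two-point sample with mean exactly 1.00 and sample SD exactly 0.05
        d = 0.05 / np.sqrt(2.0)
        assert responder_threshold([1.0 - d, 1.0 + d]) == pytest.approx(1.15)

    def test_zero_variance(self):
        assert responder_threshold([1.0, 1.0, 1.0]) == pytest.approx(1.0)

    def test_matches_mean_plus_3sd_oracle(self):
        rng = np.random.default_rng(12)
        peaks = rng.normal(1.0, 0.05, 500)
        expected = peaks.mean() + 3 * peaks.std(ddof=1)
        assert responder_threshold(peaks) == pytest.approx(expected)

    def test_translation_equivariance(self):
        rng = np.random.default_rng(14)
        peaks = rng.normal(1.0, 0.05, 100)
        assert responder_threshold(peaks + 0.2) == pytest.approx(
            responder_threshold(peaks) + 0.2
        )

    def test_needs_two_values(self):
        with pytest.raises(ValueError):
            responder_threshold([1.0])


class TestClassification:
    def make_calls(self, folds):
        return pd.DataFrame(
            {
                "neuron_id": [f"n{i}" for i in range(len(folds))],
                "stimulus": "AITC_low",
                "amplitude_fold": folds,
                "peak_fold": folds,
                "excluded_desensitized": False,
            }
        )

    @pytest.mark.parametrize(
        "fold,expected", [(1.20, True), (1.15, True), (1.00, False), (1.1499, False)]
    )
    def test_cutoff_inclusive(self, fold, expected):
        out = classify_responders(self.make_calls([fold]), cutoff=1.15)
        assert bool(out["is_responder"].iloc[0]) is expected

    def test_excluded_rows_classified_from_own_window_peak(self):
        calls = self.make_calls([1.4])
        calls["excluded_desensitized"] = True
        calls["amplitude_fold"] = np.nan
        out = classify_responders(calls)
        assert bool(out["is_responder"].iloc[0])


class TestDesensitization:
    SCHEDULE = StimulusSchedule.default()

    def _trace(self, recovery_level):
        """Low-dose peak 1.6 at 80 s, then level `recovery_level` until KCl."""
        t = times(256)
        trace = np.ones_like(t)
        low = (t >= 60) & (t <= 90)
        trace[low] = 1.6
        between = (t > 90) & (t < 240)
        trace[between] = recovery_level
        return trace, t

    def test_full_recovery_not_excluded(self):
        trace, t = self._trace(1.0)
        flags = flag_desensitized(trace, t, self.SCHEDULE)
        assert flags == {"AITC_low": False, "AITC_high": False}

    def test_stuck_at_peak_excluded(self):
        trace, t = self._trace(1.6)
        assert flag_desensitized(trace, t, self.SCHEDULE)["AITC_high"] is True

    @pytest.mark.parametrize(
        "level,excluded", [(1.25, False), (1.35, True)]  # criterion at 1 + 0.5*0.6 = 1.3
    )
    def test_recovery_criterion_boundary(self, level, excluded):
        trace, t = self._trace(level)
        assert flag_desensitized(trace, t, self.SCHEDULE)["AITC_high"] is excluded

    def test_no_prior_response_never_excluded(self):
        t = times(256)
        flags = flag_desensitized(np.ones_like(t) * 1.05, t, self.SCHEDULE)
        assert flags["AITC_high"] is False

    def test_planted_desensitization_recovered_from_generator(self):
        traces, truth = gen_traces(
            n_mice=2,
            neurons_per_mouse=60,
            responder_fraction=0.5,
            desensitize_prob=0.5,
            seed=21,
        )
        calls = analyze_traces(traces, self.SCHEDULE)
        high = calls[calls["stimulus"] == "AITC_high"].set_index("neuron_id")
        tt = truth.set_index("neuron_id")
        assert (
            high.loc[tt.index, "excluded_desensitized"] == tt["desensitized"]
        ).all()


class TestPercentResponders:
    def make_calls(self, mouse, n_aitc_resp, n_kcl_resp, n_neurons):
        rows = []
        for i in range(n_neurons):
            nid = f"{mouse}_n{i}"
            rows.append(
                {
                    "neuron_id": nid,
                    "mouse_id": mouse,
                    "stimulus": "AITC_low",
                    "amplitude_fold": 1.5 if i < n_aitc_resp else 1.0,
                    "peak_fold": 1.5 if i < n_aitc_resp else 1.0,
                    "is_responder": i < n_aitc_resp,
                    "excluded_desensitized": False,
                }
            )
            rows.append(
                {
                    "neuron_id": nid,
                    "mouse_id": mouse,
                    "stimulus": "KCl",
                    "amplitude_fold": 1.9 if i < n_kcl_resp else 1.0,
                    "peak_fold": 1.9 if i < n_kcl_resp else 1.0,
                    "is_responder": i < n_kcl_resp,
                    "excluded_desensitized": False,
                }
            )
        return pd.DataFrame(rows)

    def test_10_of_20_kcl_responders_is_50pct(self):
        calls = self.make_calls("m1", n_aitc_resp=10, n_kcl_resp=20, n_neurons=25)
        out = percent_responders(calls)
        assert out["pct_responders_AITC_low"].iloc[0] == pytest.approx(50.0)
        assert out["n_kcl_responders"].iloc[0] == 20
        assert out["n_neurons"].iloc[0] == 25

    def test_zero_responders_is_0pct(self):
        calls = self.make_calls("m1", 0, 20, 25)
        assert percent_responders(calls)["pct_responders_AITC_low"].iloc[0] == 0.0

    def test_zero_kcl_responders_missing_with_warning(self):
        calls = self.make_calls("m1", 5, 0, 10)
        with pytest.warns(RuntimeWarning, match="no KCl responders"):
            out = percent_responders(calls)
        assert np.isnan(out["pct_responders_AITC_low"].iloc[0])

    def test_gating_keeps_percentage_at_most_100(self):
        # 15 AITC responders but only 10 KCl responders: gated -> <= 100
        calls = self.make_calls("m1", 15, 10, 20)
        out = percent_responders(calls, gate_to_kcl=True)
        assert out["pct_responders_AITC_low"].iloc[0] <= 100.0
        ungated = percent_responders(calls, gate_to_kcl=False)
        assert ungated["pct_responders_AITC_low"].iloc[0] == pytest.approx(150.0)


class TestGroupCompare:
    def test_identical_groups_t_zero(self):
        t, p = group_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_two_by_two_hand_calculation(self):
        # a = [1, 3], b = [2, 6]: means 2, 4; s2p = (2 + 8) / 2 = 5
        # t = (2-4)/sqrt(5 * (1/2+1/2)) = -2/sqrt(5)
        t, p = group_compare([1.0, 3.0], [2.0, 6.0])
        assert t == pytest.approx(-2.0 / np.sqrt(5.0))

    def test_anova_matches_t_squared_for_two_groups(self):
        rng = np.random.default_rng(16)
        a, b = rng.normal(0, 1, 7), rng.normal(0, 1, 7)
        t, pt = group_compare(a, b, test="unpaired_t")
        f, pf = group_compare(a, b, test="oneway_anova")
        assert f == pytest.approx(t**2)
        assert pf == pytest.approx(pt)

    def test_unknown_test_rejected(self):
        with pytest.raises(ValueError, match="unknown test"):
            group_compare([1, 2], [3, 4], test="wilcoxon")

    def test_mouse_level_null_type_one_error(self):
        # moderate-size null check; the full 10,000-rep calibration runs in
        # the acceptance suite
        rng = np.random.default_rng(18)
        rejections = 0
        reps = 1000
        for _ in range(reps):
            _, p = group_compare(rng.normal(0, 1, 7), rng.normal(0, 1, 7))
            rejections += p < 0.05
        assert rejections / reps == pytest.approx(0.05, abs=0.02)


class TestPipeline:
    def test_analyze_traces_matches_planted_classes(self):
        traces, truth = gen_traces(
            n_mice=3, neurons_per_mouse=40, responder_fraction=0.4, seed=3
        )
        calls = analyze_traces(traces, StimulusSchedule.default())
        low = calls[calls["stimulus"] == "AITC_low"].set_index("neuron_id")
        tt = truth.set_index("neuron_id")
        agreement = (low.loc[tt.index, "is_responder"] == tt["responder"]).mean()
        assert agreement > 0.97

    def test_raw_channel_input_equivalent_to_ratio_input(self):
        traces, _ = gen_traces(n_mice=1, neurons_per_mouse=5, seed=9)
        with_channels = traces.copy()
        rng = np.random.default_rng(0)
        f380 = rng.uniform(1.0, 2.0, len(traces))
        with_channels["f340"] = traces["ratio"] * f380
        with_channels["f380"] = f380
        with_channels = with_channels.drop(columns=["ratio"])
        sched = StimulusSchedule.default()
        a = analyze_traces(traces, sched)
        b = analyze_traces(with_channels, sched)
        pd.testing.assert_series_equal(
            a["is_responder"], b["is_responder"], check_names=False
        )
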