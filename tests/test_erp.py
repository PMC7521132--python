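"""EEG pipeline: trigger decoding, filtering/downsampling, epoching,
rejection, averaging, window identification, and the TRI."""

import numpy as np
import pytest
from scipy import signal as sps

from oddbeat import erp, synth
from oddbeat.erp import (
    ComponentWindows,
    ContinuousRecording,
    EpochSet,
    EventMarkers,
    UnknownCodeError,
    average_evoked,
    baseline_correct,
    compute_tri,
    decode_triggers,
    design_lowpass_fir,
    extract_epochs,
    find_component_windows,
    grand_average,
    mean_amplitude,
    preprocess,
    reject_artifacts,
)


def pulses(samples_amps, n=10_000):
    x = np.zeros(n)
    for s, a in samples_amps:
        x[s : s + 40] = a
    return x


class TestDecodeTriggers:
    def test_two_pulses_400_ms_apart_at_4_khz(self):
        trig = pulses([(1000, 0.6), (2600, 0.2)])
        m = decode_triggers(trig, 4000.0)
        assert list(m.samples) == [1000, 2600]
        assert list(m.labels) == ["deviant", "base"]
        assert m.samples[1] - m.samples[0] == 1600

    def test_all_zero_track_yields_no_markers(self):
        m = decode_triggers(np.zeros(5000), 4000.0)
        assert len(m) == 0

    def test_base_short_code_decodes_to_base(self):
        m = decode_triggers(pulses([(100, 0.4)]), 4000.0)
        assert list(m.labels) == ["base"]

    def test_unknown_plateau_amplitude_raises(self):
        with pytest.raises(UnknownCodeError):
            decode_triggers(pulses([(100, 1.7)]), 4000.0)

    def test_amplitude_noise_within_tolerance_is_classified(self):
        rng = np.random.default_rng(0)
        trig = pulses([(500, 0.6), (3000, 0.8)]) + 0.02 * rng.standard_normal(10_000)
        m = decode_triggers(trig, 4000.0)
        keep = [l for l in m.labels if l in ("deviant", "standard_key")]
        assert keep == ["deviant", "standard_key"]


class TestFilterContract:
    def test_dc_gain_is_unity(self):
        taps = design_lowpass_fir()
        assert np.sum(taps) == pytest.approx(1.0, abs=1e-3)

    def test_fifty_hz_attenuated_by_twenty_db(self):
        taps = design_lowpass_fir()
        w, h = sps.freqz(taps, worN=4096, fs=500.0)
        gain_50 = np.abs(h[np.argmin(np.abs(w - 50.0))])
        assert 20 * np.log10(gain_50) < -20.0

    def test_passband_flat_at_low_frequency(self):
        taps = design_lowpass_fir()
        w, h = sps.freqz(taps, worN=4096, fs=500.0)
        assert np.abs(h[np.argmin(np.abs(w - 10.0))]) == pytest.approx(1.0, abs=1e-2)

    def test_impulse_response_is_symmetric(self):
        taps = design_lowpass_fir()
        np.testing.assert_allclose(taps, taps[::-1], atol=1e-15)
        assert len(taps) % 2 == 1

    def test_dc_recording_passes_through(self):
        rec = ContinuousRecording(np.full((1, 8000), 5.0), 4000.0, ["Cz"])
        out, _ = preprocess(rec)
        mid = out.channel("Cz")[200:-200]
        np.testing.assert_allclose(mid, 5.0, atol=5e-3)

    def test_fifty_hz_sinusoid_attenuated_in_pipeline(self):
        t = np.arange(40_000) / 4000.0
        rec = ContinuousRecording(10 * np.sin(2 * np.pi * 50 * t)[None, :], 4000.0, ["Cz"])
        out, _ = preprocess(rec)
        assert out.channel("Cz")[500:-500].std() < 0.1 * (10 / np.sqrt(2))

    def test_impulse_delay_compensation(self):
        k = 20_000
        x = np.zeros(40_000)
        x[k] = 1.0
        rec = ContinuousRecording(x[None, :], 4000.0, ["Cz"])
        out, _ = preprocess(rec)
        peak = int(np.argmax(np.abs(out.channel("Cz"))))
        assert abs(peak - round(k / 8)) <= 1

    def test_marker_reindexing_rounds_half_up(self):
        m = EventMarkers(np.array([0, 4, 1000, 1004]), np.array(["base"] * 4, object), 4000.0)
        rec = ContinuousRecording(np.zeros((1, 2000)), 4000.0, ["Cz"])
        _, m500 = preprocess(rec, m)
        assert list(m500.samples) == [0, 1, 125, 126]  # 4*0.125=0.5 rounds up


class TestEpoching:
    def make_rec(self, n=2000, rate=500.0):
        return ContinuousRecording(np.arange(n, dtype=float)[None, :], rate, ["Cz"])

    def test_epoch_index_arithmetic(self):
        rec = self.make_rec()
        m = EventMarkers(np.array([500]), np.array(["deviant"], object), 500.0)
        ep = extract_epochs(rec, m)
        assert ep.data.shape == (1, 250)
        np.testing.assert_array_equal(ep.data[0], np.arange(475, 725, dtype=float))

    def test_marker_near_recording_end_dropped_and_counted(self):
        rec = self.make_rec(n=1000)
        m = EventMarkers(
            np.array([500, 995]), np.array(["deviant", "deviant"], object), 500.0
        )
        ep = extract_epochs(rec, m)
        assert len(ep.labels) == 1
        assert ep.n_dropped_bounds == 1

    def test_non_key_labels_ignored(self):
        rec = self.make_rec()
        m = EventMarkers(
            np.array([300, 500, 700]),
            np.array(["base", "deviant", "standard_key"], object),
            500.0,
        )
        ep = extract_epochs(rec, m)
        assert list(ep.labels) == ["deviant", "standard_key"]

    def test_zero_key_events_is_an_error(self):
        rec = self.make_rec()
        m = EventMarkers(np.array([500]), np.array(["base"], object), 500.0)
        with pytest.raises(erp.PipelineError):
            extract_epochs(rec, m)


class TestBaselineCorrection:
    def make_epochs(self, data):
        return EpochSet(data, np.array(["deviant"] * len(data), object), 500.0, (-0.05, 0.45))

    def test_constant_epoch_becomes_zero(self):
        ep = baseline_correct(self.make_epochs(np.full((3, 250), 7.0)))
        np.testing.assert_allclose(ep.data, 0.0, atol=1e-12)

    def test_baseline_mean_is_zero_after_correction(self):
        rng = np.random.default_rng(1)
        ep = baseline_correct(self.make_epochs(rng.standard_normal((8, 250))))
        t = ep.times
        base = (t >= -0.05) & (t < 0)
        np.testing.assert_allclose(ep.data[:, base].mean(axis=1), 0.0, atol=1e-12)

    def test_offset_invariance(self):
        rng = np.random.default_rng(2)
        raw = rng.standard_normal((4, 250))
        a = baseline_correct(self.make_epochs(raw))
        b = baseline_correct(self.make_epochs(raw + 3.0))
        np.testing.assert_allclose(a.data, b.data, atol=1e-12)


class TestArtifactRejection:
    def make_epochs(self, rows):
        return EpochSet(np.array(rows, float), np.array(["deviant"] * len(rows), object),
                        500.0, (-0.05, 0.45))

    def test_threshold_is_inclusive_at_limit(self):
        ep = self.make_epochs([np.full(250, 99.0), np.r_[np.zeros(249), 101.0]])
        out, rep = reject_artifacts(ep, limit=100.0)
        assert list(out.kept) == [True, False]
        assert rep["kept"]["deviant"] == 1 and rep["rejected"]["deviant"] == 1

    def test_counts_conserved_and_monotone_in_limit(self):
        rng = np.random.default_rng(3)
        ep = self.make_epochs(list(60 * rng.standard_normal((40, 250))))
        strict, rep50 = reject_artifacts(ep, limit=50.0)
        loose, rep100 = reject_artifacts(ep, limit=100.0)
        assert rep50["kept"]["deviant"] + rep50["rejected"]["deviant"] == 40
        assert np.all(loose.kept[strict.kept])  # kept(50) subset of kept(100)

    def test_too_few_trials_flags_exclusion(self):
        ep = self.make_epochs([np.zeros(250)] * 10)
        _, rep = reject_artifacts(ep, limit=100.0, min_total=80)
        assert rep["excluded"]


class TestAveraging:
    def make_epochs(self, rows, labels):
        return EpochSet(np.array(rows, float), np.array(labels, object), 500.0, (-0.05, 0.45))

    def test_single_epoch_average_is_itself(self):
        row = np.arange(250.0)
        ep = self.make_epochs([row, np.zeros(250)], ["deviant", "standard_key"])
        ev = average_evoked(ep)
        np.testing.assert_array_equal(ev["deviant"], row)

    def test_opposite_epochs_cancel(self):
        row = np.sin(np.arange(250.0))
        ep = self.make_epochs([row, -row, np.zeros(250)],
                              ["deviant", "deviant", "standard_key"])
        np.testing.assert_allclose(average_evoked(ep)["deviant"], 0.0, atol=1e-12)

    def test_rejected_epochs_excluded_from_average(self):
        ep = self.make_epochs([np.full(250, 200.0), np.full(250, 2.0), np.zeros(250)],
                              ["deviant", "deviant", "standard_key"])
        ep, _ = reject_artifacts(ep, limit=100.0, min_total=1)
        np.testing.assert_allclose(average_evoked(ep)["deviant"], 2.0)

    def test_grand_average_of_identical_subjects_is_idempotent(self):
        ev = {"deviant": np.arange(10.0), "standard": np.ones(10)}
        g = grand_average([ev, ev, ev])
        np.testing.assert_allclose(g["deviant"], ev["deviant"])


class TestComponentWindows:
    def bump_wave(self, times, n1_lat, p2_lat, width=0.004):
        w = np.zeros_like(times)
        w[np.argmin(np.abs(times - n1_lat))] = -5.0
        w[np.argmin(np.abs(times - p2_lat))] = 5.0
        return w

    def test_peaks_recovered_and_windows_opened(self):
        times = -0.05 + np.arange(250) / 500.0
        grand = {
            "standard": self.bump_wave(times, 0.122, 0.174),
            "deviant": self.bump_wave(times, 0.138, 0.216),
        }
        w = find_component_windows(grand, times)
        assert w.n1_lat["standard"] == pytest.approx(0.122)
        assert w.p2_lat["deviant"] == pytest.approx(0.216)
        assert w.n1_window["standard"] == (pytest.approx(0.072), pytest.approx(0.172))

    def test_ties_break_to_earliest_latency(self):
        times = -0.05 + np.arange(250) / 500.0
        flat = np.zeros_like(times)
        w = find_component_windows({"standard": flat, "deviant": flat}, times)
        assert w.n1_lat["standard"] == pytest.approx(0.050)

    def test_windows_clip_to_epoch_bounds(self):
        # short epoch and early N1 search force both window edges to clip
        times = -0.05 + np.arange(150) / 500.0  # ends at 248 ms
        grand = {"standard": self.bump_wave(times, 0.0, 0.240),
                 "deviant": self.bump_wave(times, 0.0, 0.240)}
        w = find_component_windows(grand, times, n1_search=(-0.02, 0.1), p2_max=0.248)
        assert w.n1_window["standard"][0] == pytest.approx(times[0])
        assert w.p2_window["standard"][1] == pytest.approx(times[-1])


class TestComputeTri:
    def constant_windows(self, times):
        return ComponentWindows(
            n1_lat={"deviant": 0.138, "standard": 0.122},
            p2_lat={"deviant": 0.216, "standard": 0.174},
            n1_window={"deviant": (0.088, 0.188), "standard": (0.072, 0.172)},
            p2_window={"deviant": (0.166, 0.266), "standard": (0.124, 0.224)},
            halfwidth=0.050,
        )

    def step_wave(self, times, n1_win, p2_win, n1_val, p2_val):
        w = np.zeros_like(times)
        w[(times >= n1_win[0]) & (times <= n1_win[1])] = n1_val
        w[(times >= p2_win[0]) & (times <= p2_win[1])] = p2_val
        return w

    def test_magnitudes_and_difference_arithmetic(self):
        times = -0.05 + np.arange(250) / 500.0
        w = self.constant_windows(times)
        # non-overlapping halves of each window carry the N1/P2 values
        evoked = {
            "deviant": self.step_wave(times, (0.088, 0.160), (0.166, 0.266), -2.0, 3.0),
            "standard": self.step_wave(times, (0.072, 0.120), (0.124, 0.224), -1.0, 1.0),
        }
        # means over the full windows differ from the plateau values; use
        # brute-force means as the oracle
        r = compute_tri(evoked, times, w, variant="mean50")
        for cond in ("deviant", "standard"):
            mask_n1 = (times >= w.n1_window[cond][0] - 1e-9) & (times <= w.n1_window[cond][1] + 1e-9)
            mask_p2 = (times >= w.p2_window[cond][0] - 1e-9) & (times <= w.p2_window[cond][1] + 1e-9)
            assert r.n1_mean[cond] == pytest.approx(evoked[cond][mask_n1].mean(), abs=1e-12)
            assert r.p2_mean[cond] == pytest.approx(evoked[cond][mask_p2].mean(), abs=1e-12)
            assert r.magnitude[cond] == pytest.approx(r.p2_mean[cond] - r.n1_mean[cond], abs=1e-12)
        assert r.tri == pytest.approx(r.magnitude["deviant"] - r.magnitude["standard"], abs=1e-12)

    def test_identical_conditions_and_windows_give_zero_tri(self):
        times = -0.05 + np.arange(250) / 500.0
        wave = np.sin(20 * times)
        same = ComponentWindows(
            n1_lat={"deviant": 0.122, "standard": 0.122},
            p2_lat={"deviant": 0.174, "standard": 0.174},
            n1_window={"deviant": (0.072, 0.172), "standard": (0.072, 0.172)},
            p2_window={"deviant": (0.124, 0.224), "standard": (0.124, 0.224)},
            halfwidth=0.050,
        )
        for variant in ("mean50", "peak", "peak_mean20"):
            r = compute_tri({"deviant": wave, "standard": wave.copy()},
                            times, same, variant=variant)
            assert r.tri == pytest.approx(0.0, abs=1e-12)

    def test_peak_variant_takes_extreme_voltages(self):
        times = -0.05 + np.arange(250) / 500.0
        w = self.constant_windows(times)
        evoked = {
            "deviant": self.step_wave(times, (0.100, 0.140), (0.180, 0.220), -4.0, 5.0),
            "standard": self.step_wave(times, (0.090, 0.130), (0.140, 0.200), -1.0, 2.0),
        }
        r = compute_tri(evoked, times, w, variant="peak")
        assert r.n1_mean["deviant"] == -4.0 and r.p2_mean["deviant"] == 5.0
        assert r.tri == pytest.approx(9.0 - 3.0)

    def test_unknown_variant_rejected(self):
        times = -0.05 + np.arange(250) / 500.0
        with pytest.raises(ValueError):
            compute_tri({}, times, self.constant_windows(times), variant="median")


def test_mean_amplitude_is_brute_force_sample_mean():
    rng = np.random.default_rng(4)
    times = -0.05 + np.arange(250) / 500.0
    wave = rng.standard_normal(250)
    window = (0.072, 0.172)
    mask = (times >= window[0] - 1e-9) & (times <= window[1] + 1e-9)
    assert mean_amplitude(wave, times, window) == pytest.approx(wave[mask].mean(), abs=1e-12)


class TestNoiselessPipelineIdentity:
    def test_component_latencies_match_generator(self, noiseless_subject):
        params, _, _, windows = noiseless_subject
        for cond, is_dev in (("standard", False), ("deviant", True)):
            n1_true, p2_true = synth.kernel_extrema(params, is_dev)
            assert abs(windows.n1_lat[cond] - n1_true) <= 1 / 500.0 + 1e-9
            assert abs(windows.p2_lat[cond] - p2_true) <= 1 / 500.0 + 1e-9

    def test_tri_over_standard_magnitude_recovers_gain(self, noiseless_subject):
        params, evoked, times, windows = noiseless_subject
        r = compute_tri(evoked, times, windows, variant="mean50")
        assert r.tri / r.magnitude["standard"] == pytest.approx(params.gain, rel=0.05)

    def test_tri_ordering_follows_gain_ordering(self, small_plan):
        from oddbeat.stats import spearman

        gains = [0.2, 0.8, 1.4, 2.0]
        tris = []
        for g in gains:
            params = synth.SubjectParams(gain=g, noise_sd=0.0)
            rec = synth.simulate_recording(small_plan, params, rate=500.0, seed=0)
            markers = decode_triggers(rec.channel("TRIG"), rec.rate)
            rec500, m500 = preprocess(rec, markers)
            ep = baseline_correct(extract_epochs(rec500, m500))
            ep, _ = reject_artifacts(ep)
            evoked = average_evoked(ep)
            w = find_component_windows(evoked, ep.times)
            tris.append(compute_tri(evoked, ep.times, w).tri)
        assert spearman(gains, tris).statistic == pytest.approx(1.0)
        assert np.all(np.diff(tris) > 0)
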