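import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from runzc.event_detection import (
    GaitEvent,
    InsufficientDataError,
    StepTiming,
    ThresholdSpec,
    detect_final_contact,
    detect_initial_contacts,
    dynamic_threshold,
    pair_steps,
    refine_events,
    samples_to_ms,
    zc_gradient_peaks,
)
from runzc.pipeline import run_gait_analysis
from runzc.preprocess import bandpass_recording
from runzc.simulator import SimulationSpec, simulate_bout

from conftest import make_recording
from oracles import brute_force_zc_peaks, rolling_max_oracle

FS = 60.0
NO_REFRACTORY = ThresholdSpec(refractory_fraction=None)


class TestDynamicThreshold:
    def test_constant_series(self):
        thr = dynamic_threshold(np.full(50, 3.0), FS, ThresholdSpec(maxima_fraction=0.4))
        np.testing.assert_allclose(thr, 1.2)

    def test_window_covering_whole_series(self):
        x = np.array([0.0, 1.0, 3.0, 1.0, 0.0])
        thr = dynamic_threshold(x, FS, ThresholdSpec(maxima_fraction=0.4, maxima_window_s=10.0))
        np.testing.assert_allclose(thr, 1.2)

    def test_adapts_per_window_against_naive_rolling_max(self):
        rng = np.random.default_rng(5)
        x = np.concatenate([2.0 * rng.uniform(0.5, 1.0, 120), 4.0 * rng.uniform(0.5, 1.0, 120)])
        spec = ThresholdSpec(maxima_fraction=0.4, maxima_window_s=1.0)
        thr = dynamic_threshold(x, FS, spec)
        expected = 0.4 * np.asarray(rolling_max_oracle(x, FS, 1.0))
        np.testing.assert_allclose(thr, expected, atol=1e-12)

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            dynamic_threshold(np.array([]), FS)


class TestZcGradientPeaks:
    def test_enumerated_two_peak_signal(self):
        assert zc_gradient_peaks([0, 1, 0, 1, 0], FS, NO_REFRACTORY) == [1, 3]

    def test_monotone_series_has_no_peaks(self):
        assert zc_gradient_peaks(np.arange(20.0), FS) == []

    def test_constant_series_has_no_peaks(self):
        assert zc_gradient_peaks(np.full(20, 2.0), FS) == []

    def test_plateau_yields_first_index(self):
        assert zc_gradient_peaks([0, 2, 2, 2, 0], FS, NO_REFRACTORY) == [1]

    def test_minimum_length_enforced(self):
        with pytest.raises(ValueError, match="3 samples"):
            zc_gradient_peaks([0.0, 1.0], FS)

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_brute_force_oracle_on_noisy_multipeak_signals(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 1001))
        # mixture of periodic peaks and noise exercises threshold + refractory
        t = np.arange(n) / FS
        x = np.sin(2 * np.pi * rng.uniform(1, 4) * t) + rng.normal(0, rng.uniform(0.1, 1.0), n)
        spec = ThresholdSpec()
        got = zc_gradient_peaks(x, FS, spec)
        expected = brute_force_zc_peaks(x, FS, spec.maxima_fraction,
                                        spec.maxima_window_s, spec.refractory_fraction)
        assert got == expected

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        x=hnp.arrays(
            np.float64,
            st.integers(10, 200),
            elements=st.floats(-10, 10, allow_nan=False, width=32),
        )
    )
    def test_oracle_equivalence_property(self, x):
        got = zc_gradient_peaks(x, FS)
        assert got == brute_force_zc_peaks(x, FS)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(scale=st.floats(1e-3, 1e3, allow_nan=False), seed=st.integers(0, 1000))
    def test_scale_invariance(self, scale, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, 300) + np.sin(np.arange(300) / 5.0)
        assert zc_gradient_peaks(x, FS) == zc_gradient_peaks(scale * x, FS)

    def test_determinism(self):
        x = np.random.default_rng(1).normal(size=500)
        assert zc_gradient_peaks(x, FS) == zc_gradient_peaks(x, FS)


class TestSamplesToMs:
    @pytest.mark.parametrize(
        "n,fs,expected",
        [(38, 200.0, 190), (11, 60.0, 183), (0, 60.0, 0), (30, 60.0, 500)],
    )
    def test_worked_conversions(self, n, fs, expected):
        assert samples_to_ms(n, fs) == expected

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            samples_to_ms(-1, 60.0)


class TestInitialContacts:
    def test_short_recording_rejected(self):
        rec = make_recording(n=60)
        with pytest.raises(InsufficientDataError):
            detect_initial_contacts(rec)

    def test_all_zero_signal_yields_no_events(self):
        rec = make_recording(n=300)
        assert detect_initial_contacts(rec) == []

    def test_noise_free_bout_recovers_every_impact(self, analyzed_bout):
        analysis, truth, recording = analyzed_bout
        assert len(analysis.ics) == truth.n_steps
        truth_idx = np.round(truth.ic_times_s * recording.fs_hz).astype(int)
        got_idx = np.array([e.sample_index for e in analysis.ics])
        assert np.max(np.abs(got_idx - truth_idx)) <= 1

    def test_ringing_without_refractory_overestimates_event_count(self):
        # high post-impact oscillation on the raw signal: the scan finds
        # ringing peaks as extra events unless the refractory pass prunes them
        rec, truth = simulate_bout(
            SimulationSpec(speed_kmh=14, n_steps=20, ringing_gain=1.0, noise_acc_g=0.0, seed=2)
        )
        events = detect_initial_contacts(rec, NO_REFRACTORY)
        assert len(events) >= truth.n_steps

    def test_event_times_strictly_increasing(self, analyzed_bout):
        analysis, _, _ = analyzed_bout
        times = [e.time_s for e in analysis.ics]
        assert all(b > a for a, b in zip(times, times[1:]))


class TestFinalContact:
    @staticmethod
    def _step_recording(trough_at=117, trough_depth=-1.5, n=240):
        t = np.arange(n) / FS
        acc = 3.0 * np.exp(-0.5 * ((t - 100 / FS) / 0.011) ** 2)
        acc += trough_depth * np.exp(-0.5 * ((t - trough_at / FS) / 0.014) ** 2)
        return make_recording(n=n, acc_vert=acc)

    def test_trough_in_roi_found_exactly(self):
        rec = self._step_recording(trough_at=117)
        ic = GaitEvent(100, 100 / FS, "IC", float(rec.acc_vert[100]))
        fc = detect_final_contact(rec, ic)
        assert fc is not None and fc.sample_index == 117

    def test_non_negative_roi_yields_absent(self):
        rec = make_recording(n=240, acc_vert=np.abs(np.sin(np.arange(240) / 3.0)))
        ic = GaitEvent(100, 100 / FS, "IC", 1.0)
        assert detect_final_contact(rec, ic) is None

    def test_trough_past_roi_is_ignored(self):
        rec = self._step_recording(trough_at=132)  # 32 samples = 533 ms after IC
        ic = GaitEvent(100, 100 / FS, "IC", float(rec.acc_vert[100]))
        assert detect_final_contact(rec, ic) is None

    def test_ic_at_final_sample_absent(self):
        rec = make_recording(n=120)
        ic = GaitEvent(119, 119 / FS, "IC", 0.0)
        assert detect_final_contact(rec, ic) is None


class TestPairSteps:
    def test_worked_gct_conversion(self):
        # IC at 0, FC at 11 at 60 Hz: 183 ms, matching the printed resampling example
        rec = self._two_event_recording()
        ics = [GaitEvent(0, 0.0, "IC", float(rec.acc_vert[0]))]
        timings = pair_steps(ics, rec, min_gct_ms=100.0)
        assert timings[0].fc is not None and timings[0].fc.sample_index == 11
        assert timings[0].gct_ms == 183

    @staticmethod
    def _two_event_recording(n=240):
        t = np.arange(n) / FS
        acc = 3.0 * np.exp(-0.5 * (t / 0.011) ** 2)
        acc += -1.5 * np.exp(-0.5 * ((t - 11 / FS) / 0.014) ** 2)
        return make_recording(n=n, acc_vert=acc)

    def test_unpaired_ic_has_absent_fc_and_gct(self):
        rec = make_recording(n=240)
        ics = [GaitEvent(10, 10 / FS, "IC", 0.0)]
        timings = pair_steps(ics, rec)
        assert timings[0].fc is None and timings[0].gct_ms is None

    def test_simulated_gct_within_one_sample_period(self):
        rec, truth = simulate_bout(
            SimulationSpec(speed_kmh=12, n_steps=20, noise_acc_g=0.0, seed=9)
        )
        analysis = run_gait_analysis(rec)
        got = [s.gct_ms for s in analysis.timings if s.gct_ms is not None]
        assert len(got) == truth.n_steps
        assert np.max(np.abs(np.asarray(got) - truth.gct_ms)) <= 1000.0 / rec.fs_hz

    def test_step_timing_invariants_enforced(self):
        ic = GaitEvent(10, 10 / FS, "IC", 1.0)
        with pytest.raises(ValueError, match="gct_ms"):
            StepTiming(ic=ic, fc=GaitEvent(20, 20 / FS, "FC", -1.0), gct_ms=None)
        with pytest.raises(ValueError, match="after"):
            StepTiming(ic=ic, fc=GaitEvent(5, 5 / FS, "FC", -1.0), gct_ms=100)
        with pytest.raises(ValueError, match="region of interest"):
            StepTiming(ic=ic, fc=GaitEvent(50, 50 / FS, "FC", -1.0), gct_ms=667)


class TestRefineEvents:
    def test_snaps_to_local_extremum_of_reference_series(self):
        x = np.zeros(50)
        x[20] = 5.0
        events = [GaitEvent(18, 18 / FS, "IC", 0.0)]
        refined = refine_events(events, x, FS, radius=2)
        assert refined[0].sample_index == 20
        assert refined[0].peak_value == 5.0

    def test_coincident_refinements_are_merged(self):
        x = np.zeros(50)
        x[20] = 5.0
        events = [GaitEvent(19, 19 / FS, "IC", 0.0), GaitEvent(21, 21 / FS, "IC", 0.0)]
        assert len(refine_events(events, x, FS, radius=2)) == 1

    def test_filtered_candidates_refine_onto_raw_impacts(self, noise_free_bout):
        recording, truth = noise_free_bout
        filtered = bandpass_recording(recording)
        candidates = detect_initial_contacts(filtered)
        refined = refine_events(candidates, recording.acc_vert, recording.fs_hz, radius=2)
        truth_idx = np.round(truth.ic_times_s * recording.fs_hz).astype(int)
        got = np.array([e.sample_index for e in refined])
        assert got.size == truth_idx.size
        assert np.max(np.abs(got - truth_idx)) <= 1
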