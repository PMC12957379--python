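"""Triggered-droplet simulation, trace analysis and lock-in metrics."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from dropmix import (DropletEvents, HitSeries, OscillatorConfig,
                     TriggerConfig, annotate_hits, detect_events,
                     fold_waterfall, hit_rate, lock_in_report,
                     simulate_droplets, synth_trace)
from dropmix.sync import circular_sd_seconds, window_phases


def jittery_osc(f0=10.05, jitter=0.002):
    return OscillatorConfig(natural_frequency=f0, period_jitter_sd=jitter,
                            phase0=0.025)


class TestSimulate:
    def test_deterministic_given_seed(self):
        osc = jittery_osc()
        e1 = simulate_droplets(osc, TriggerConfig(), 30.0, seed=7)
        e2 = simulate_droplets(osc, TriggerConfig(), 30.0, seed=7)
        assert np.array_equal(e1.times, e2.times)

    def test_noise_free_untriggered_is_periodic(self):
        osc = OscillatorConfig(natural_frequency=10.0, phase0=0.0)
        events = simulate_droplets(osc, TriggerConfig(amplitude=0.0), 5.0,
                                   seed=0)
        assert np.allclose(np.diff(events.times), 0.1)

    def test_strong_trigger_locks(self):
        """Full-amplitude trigger: phases settle on the trigger delay with
        sub-millisecond circular spread."""
        events = simulate_droplets(jittery_osc(), TriggerConfig(amplitude=180.0),
                                   60.0, seed=1)
        report = lock_in_report(events)
        assert report.locked_fraction > 0.95
        assert report.circular_sd < 0.001
        phases = report.per_window_phase
        assert np.nanmedian(phases) == pytest.approx(0.030, abs=1e-6)

    def test_weak_trigger_fails_to_lock(self):
        strong = lock_in_report(simulate_droplets(
            jittery_osc(), TriggerConfig(amplitude=180.0), 60.0, seed=1))
        weak = lock_in_report(simulate_droplets(
            jittery_osc(), TriggerConfig(amplitude=40.0), 60.0, seed=1))
        assert weak.locked_fraction < strong.locked_fraction - 0.3

    def test_locked_fraction_increases_with_amplitude(self):
        """Rank correlation between trigger amplitude and mean locked
        fraction over repeated seeds is positive."""
        amplitudes = [0.0, 40.0, 110.0, 180.0]
        means = []
        for amp in amplitudes:
            fracs = [
                lock_in_report(simulate_droplets(
                    jittery_osc(10.15), TriggerConfig(amplitude=amp),
                    60.0, seed=s)).locked_fraction
                for s in range(20)
            ]
            means.append(np.mean(fracs))
        rho, _ = spearmanr(amplitudes, means)
        assert rho > 0
        assert means[-1] > 0.95

    def test_capture_resets_phase_within_one_window(self):
        """With ample capture width, a full-amplitude trigger pins the
        firing to the trigger delay from the first captured window on."""
        osc = OscillatorConfig(natural_frequency=10.0, phase0=0.025)
        trig = TriggerConfig(amplitude=180.0, capture_width=0.02)
        events = simulate_droplets(osc, trig, 3.0, seed=0)
        phases = window_phases(events)
        assert np.allclose(phases[1:], trig.delay)

    def test_event_ordering_invariant(self):
        events = simulate_droplets(jittery_osc(10.15, 0.003),
                                   TriggerConfig(amplitude=110.0), 30.0,
                                   seed=11)
        assert np.all(np.diff(events.times) > 0)


class TestTraceRoundTrip:
    def test_single_pulse(self):
        events = DropletEvents(times=np.array([0.05]), duration=0.2)
        trace = synth_trace(events, noise_sd=0.0)
        assert trace.samples.max() == pytest.approx(1.0)
        assert (trace.samples > 0.5).sum() == 20  # 2 ms at 10 kHz

    def test_no_events_pure_noise(self):
        events = DropletEvents(times=np.array([]), duration=1.0)
        trace = synth_trace(events, noise_sd=0.1, seed=3)
        assert abs(trace.samples.mean()) < 0.02

    def test_round_trip_recovers_times(self):
        events = simulate_droplets(jittery_osc(), TriggerConfig(), 30.0,
                                   seed=5)
        trace = synth_trace(events, noise_sd=0.05, seed=6)  # SNR 20
        detected = detect_events(trace, threshold=0.5)
        assert detected.times.size == events.times.size
        assert np.max(np.abs(detected.times - events.times)) <= \
            1.0 / trace.sample_rate

    def test_threshold_above_amplitude_finds_nothing(self):
        events = DropletEvents(times=np.array([0.05, 0.15]), duration=0.3)
        trace = synth_trace(events, noise_sd=0.0)
        assert detect_events(trace, threshold=2.0).times.size == 0

    def test_refractory_merges_close_pulses(self):
        events = DropletEvents(times=np.array([0.050, 0.0508]), duration=0.2)
        trace = synth_trace(events, pulse_width=0.002, noise_sd=0.0)
        detected = detect_events(trace, threshold=0.5, holdoff=0.002)
        assert detected.times.size == 1

    def test_too_coarse_sampling_rejected(self):
        events = DropletEvents(times=np.array([0.05]), duration=0.2)
        with pytest.raises(ValueError):
            synth_trace(events, pulse_width=0.0001, sample_rate=10_000.0)


class TestWaterfall:
    def test_event_count_preserved(self):
        events = simulate_droplets(jittery_osc(10.15), TriggerConfig(), 30.0,
                                   seed=2)
        wf = fold_waterfall(events)
        in_rows = (events.times < wf.n_windows * wf.window_length).sum()
        assert wf.matrix.sum() == in_rows

    def test_locked_events_form_single_column(self):
        times = np.arange(50) * 0.1 + 0.030
        events = DropletEvents(times=times, duration=5.0)
        wf = fold_waterfall(events)
        cols = wf.matrix.nonzero()[1]
        assert np.unique(cols).size == 1
        assert cols[0] == int(0.030 / wf.bin_width)

    def test_free_running_phase_walk(self):
        """A 10.2 Hz free-runner walks (1/10.2 − 1/10) s per window."""
        period = 1 / 10.2
        times = np.arange(1, 200) * period
        events = DropletEvents(times=times, duration=20.0)
        phases = window_phases(events)
        walk = np.diff(phases)
        walk = walk[np.isfinite(walk) & (np.abs(walk) < 0.05)]  # drop wraps
        assert np.allclose(walk, period - 0.1, atol=1e-9)

    def test_single_window_trace(self):
        trace = synth_trace(DropletEvents(times=np.array([0.03]),
                                          duration=0.1), noise_sd=0.0)
        wf = fold_waterfall(trace)
        assert wf.matrix.shape == (1, 1000)

    def test_trace_window_must_hold_integer_samples(self):
        trace = synth_trace(DropletEvents(times=np.array([0.03]),
                                          duration=1.0),
                            noise_sd=0.0, sample_rate=10_000.0)
        with pytest.raises(ValueError):
            fold_waterfall(trace, window_length=0.10005)


class TestLockInReport:
    def test_constant_phase(self):
        times = np.arange(30) * 0.1 + 0.04
        report = lock_in_report(DropletEvents(times=times, duration=3.0))
        assert report.circular_sd == pytest.approx(0.0, abs=1e-12)
        assert report.locked_fraction == 1.0
        assert report.longest_locked_run > 20

    def test_uniform_phases_not_locked(self):
        rng = np.random.default_rng(0)
        times = np.sort(np.arange(200) * 0.1 + rng.uniform(0, 0.1, 200))
        times = times[np.concatenate(([True], np.diff(times) > 0))]
        report = lock_in_report(DropletEvents(times=times,
                                              duration=20.0))
        assert report.circular_sd > 0.01
        assert report.locked_fraction < 0.2

    def test_empty_windows_excluded(self):
        times = np.array([0.03, 0.13, 0.43, 0.53])  # windows 2,3 empty
        phases = window_phases(DropletEvents(times=times, duration=0.6))
        assert np.isnan(phases[2]) and np.isnan(phases[3])
        assert np.isfinite(phases[[0, 1, 4, 5]]).all()

    def test_circular_sd_handles_wraparound(self):
        """Phases straddling the window boundary stay tight on the circle."""
        phases = np.array([0.099, 0.001, 0.0995, 0.0005])
        sd = circular_sd_seconds(phases, 0.1)
        assert sd < 0.002


class TestHits:
    def test_annotate_requires_matching_length(self):
        events = DropletEvents(times=np.arange(10) * 0.1 + 0.03,
                               duration=1.0)
        wf = fold_waterfall(events)
        with pytest.raises(ValueError):
            annotate_hits(wf, HitSeries(hits_per_train=np.zeros(5, dtype=int)))

    def test_annotate_flags_rows(self):
        events = DropletEvents(times=np.arange(10) * 0.1 + 0.03,
                               duration=1.0)
        wf = fold_waterfall(events)
        hits = np.zeros(10, dtype=int)
        hits[4] = 3
        annotated = annotate_hits(wf, HitSeries(hits_per_train=hits))
        assert (annotated.hits > 0).sum() == 1

    @pytest.mark.parametrize("n_patterns, n_trains, pulses, rate", [
        (1631, 2018, 202, 0.0040),
        (0, 2018, 202, 0.0),
        (202, 1, 202, 1.0),
    ])
    def test_hit_rate(self, n_patterns, n_trains, pulses, rate):
        assert hit_rate(n_patterns, n_trains, pulses) == \
            pytest.approx(rate, abs=5e-5)

    def test_hit_rate_zero_denominator(self):
        with pytest.raises(ValueError):
            hit_rate(10, 0, 202)
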