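import math

import numpy as np
import pytest
from scipy.signal import butter, sosfreqz

import alpc
from alpc.preprocess import (
    EpochedRecording,
    extract_trial_phases,
    reject_bad_trials,
    rereference_car,
    zero_phase_filter,
)

TWO_PI = 2.0 * math.pi
FS = 500.0


def _recording(data, fs=FS, **kw):
    return EpochedRecording(data=np.asarray(data, dtype=float), fs_hz=fs, **kw)


def _tone_trials(n_trials, n_channels, duration, freq, fs=FS, delay=0.0,
                 channel_gains=None):
    t = np.arange(int(duration * fs)) / fs
    tone = np.cos(TWO_PI * freq * (t - delay))
    gains = np.ones(n_channels) if channel_gains is None else np.asarray(channel_gains)
    data = np.tile(tone, (n_trials, n_channels, 1)) * gains[None, :, None]
    return _recording(data)


class TestCar:
    def test_constant_offsets_cancel(self):
        data = np.zeros((2, 3, 100))
        data[:, 0] += 1.0
        data[:, 1] += 2.0
        data[:, 2] += 3.0
        rec = rereference_car(_recording(data))
        assert np.allclose(rec.data[:, :, :] - rec.data.mean(axis=1, keepdims=True),
                           rec.data)
        assert rec.car_applied

    def test_channel_sum_is_zero(self, rng):
        rec = rereference_car(_recording(rng.normal(size=(3, 5, 200))))
        assert np.allclose(rec.data.sum(axis=1), 0.0, atol=1e-12)

    def test_61_of_64_channels(self, rng):
        names = tuple(f"E{i}" for i in range(61))
        rec = _recording(rng.normal(size=(2, 61, 100)), channel_names=names)
        out = rereference_car(rec)
        assert out.n_channels == 61

    def test_single_channel_rejected(self):
        with pytest.raises(ValueError):
            rereference_car(_recording(np.zeros((2, 1, 50))))

    def test_phase_preserved_when_component_missing_from_mean(self):
        # equal-magnitude, opposite-sign loading: the channel mean carries
        # none of the component, so CAR leaves its phase untouched
        rec = _tone_trials(1, 2, 2.0, 20.0, delay=0.004,
                           channel_gains=(1.0, -1.0))
        out = rereference_car(rec)
        m = alpc.extract_phases(out.data[0, 0], FS, [20.0], 0.0, 2.0)
        assert m.measured_phases[0] == pytest.approx(
            (-TWO_PI * 20 * 0.004) % TWO_PI, abs=1e-9
        )


class TestZeroPhaseFilter:
    def test_steady_state_phase_preserved(self, rng):
        rec = _tone_trials(1, 2, 4.0, 40.0, delay=0.003)
        noisy = _recording(rec.data + 0.1 * rng.normal(size=rec.data.shape))
        out = zero_phase_filter(noisy)
        m = alpc.extract_phases(out.data[0, 0], FS, [40.0],
                                window_start=1.0, window_length=2.0)
        clean = alpc.extract_phases(rec.data[0, 0], FS, [40.0],
                                    window_start=1.0, window_length=2.0)
        delta = abs(m.measured_phases[0] - clean.measured_phases[0])
        assert min(delta, TWO_PI - delta) < 1e-2  # noise floor dominates

    def test_line_component_attenuated(self):
        rec = _tone_trials(1, 2, 4.0, 50.0)
        out = zero_phase_filter(rec)
        m = alpc.extract_phases(out.data[0, 0], FS, [50.0], 1.0, 2.0)
        assert 20 * math.log10(m.amplitudes[0]) < -30.0

    def test_drift_attenuated_by_60_db(self):
        # evaluate the forward-backward high-pass response at 0.1 Hz
        sos = butter(10, 1.0, btype="highpass", fs=FS, output="sos")
        w, h = sosfreqz(sos, worN=[0.1], fs=FS)
        assert 20 * math.log10(np.abs(h[0]) ** 2) < -60.0

    def test_zero_phase_on_pure_tone(self):
        rec = _tone_trials(1, 2, 4.0, 40.0)
        out = zero_phase_filter(rec, notch_hz=50.0)
        m = alpc.extract_phases(out.data[0, 0], FS, [40.0], 1.0, 2.0)
        assert m.measured_phases[0] == pytest.approx(0.0, abs=1e-3)

    def test_cutoff_above_nyquist(self):
        rec = _tone_trials(1, 2, 1.0, 40.0)
        with pytest.raises(ValueError):
            zero_phase_filter(rec, highpass_hz=300.0)


class TestRejectBadTrials:
    def test_identical_trials_keep_all(self):
        rec = _tone_trials(20, 3, 1.0, 10.0)
        out = reject_bad_trials(rec)
        assert out.exclusions == ()
        assert out.retained_trials == tuple(range(20))

    def test_scaled_trial_excluded(self, rng):
        data = rng.normal(size=(20, 4, 500))
        data[7] *= 10.0
        out = reject_bad_trials(_recording(data))
        assert out.excluded_trials == (7,)

    def test_cap_limits_exclusions(self, rng):
        data = rng.normal(size=(100, 4, 200))
        data[:10] *= 25.0  # ten gross artifacts
        out = reject_bad_trials(_recording(data), cap_fraction=0.05)
        assert len(out.exclusions) == 5
        assert set(out.excluded_trials) <= set(range(10))

    def test_variance_indicator_triggers(self, rng):
        data = rng.normal(size=(30, 6, 300))
        data[11, 0] *= 40.0  # one channel blown up: variance outlier
        out = reject_bad_trials(_recording(data))
        assert 11 in out.excluded_trials

    def test_too_few_trials(self):
        with pytest.raises(ValueError):
            reject_bad_trials(_tone_trials(3, 2, 1.0, 10.0))


class TestExtractTrialPhases:
    def test_methods_agree_on_identical_epochs(self):
        rec = _tone_trials(4, 2, 2.3, 10.0, delay=0.007)
        m_eeg, t1 = extract_trial_phases(rec, [10.0], method="avg_eeg")
        m_phase, t2 = extract_trial_phases(rec, [10.0], method="avg_phase")
        assert m_eeg.measured_phases[0] == pytest.approx(
            m_phase.measured_phases[0], abs=1e-9
        )
        assert t1.n_epochs == t2.n_epochs == 4 * 2

    def test_amplitude_weighting_difference(self):
        # epochs with amplitudes (10, 1) and phases (0, pi/2): the signal
        # average weights by amplitude, the phase average does not
        fs = 100.0
        t = np.arange(int(1.3 * fs)) / fs
        e1 = 10.0 * np.cos(TWO_PI * 5 * t)
        e2 = 1.0 * np.cos(TWO_PI * 5 * t + math.pi / 2)
        data = np.stack([e1, e2])[:, None, :]
        rec = _recording(data, fs=fs)
        m_eeg, _ = extract_trial_phases(rec, [5.0], method="avg_eeg",
                                        onset_skip_s=0.3, epoch_s=1.0)
        m_phase, _ = extract_trial_phases(rec, [5.0], method="avg_phase",
                                          onset_skip_s=0.3, epoch_s=1.0)
        # (phases referenced at the 0.3-s window start: 5 Hz * 0.3 s = 1.5
        # cycles shifts both by pi)
        assert m_phase.measured_phases[0] == pytest.approx(
            math.pi + math.pi / 4, abs=1e-9
        )
        assert m_eeg.measured_phases[0] == pytest.approx(
            math.pi + math.atan2(1.0, 10.0), abs=1e-9
        )

    def test_onset_skip_never_enters_epochs(self):
        fs = 100.0
        n = round(2.3 * fs)
        data = np.zeros((1, 1, n))
        data[0, 0, : int(0.3 * fs)] = 1e6  # garbage confined to the skip
        t = np.arange(n) / fs
        data[0, 0, int(0.3 * fs):] = np.cos(TWO_PI * 5 * t[int(0.3 * fs):])
        rec = _recording(data, fs=fs)
        m, table = extract_trial_phases(rec, [5.0], onset_skip_s=0.3, epoch_s=1.0)
        assert table.n_epochs == 2
        assert m.amplitudes[0] == pytest.approx(1.0, abs=1e-9)

    def test_excluded_trials_dropped(self, rng):
        data = rng.normal(size=(6, 2, 260))
        rec = _recording(data, fs=100.0)
        rec = reject_bad_trials(
            _recording(np.concatenate([data, 30 * rng.normal(size=(1, 2, 260))]),
                       fs=100.0),
            cap_fraction=0.2,
        )
        assert 6 in rec.excluded_trials
        m, table = extract_trial_phases(rec, [5.0], onset_skip_s=0.3, epoch_s=1.0)
        assert table.n_epochs == 2 * 6  # only retained trials contribute

    def test_bad_method(self):
        rec = _tone_trials(2, 2, 2.0, 10.0)
        with pytest.raises(ValueError):
            extract_trial_phases(rec, [10.0], method="median")


def _pink_noise(rng, n, fs):
    spec = np.fft.rfft(rng.normal(size=n))
    f = np.fft.rfftfreq(n, 1 / fs)
    spec[1:] /= np.sqrt(f[1:])
    spec[0] = 0.0
    return np.fft.irfft(spec, n)


def test_end_to_end_multichannel_recovery(rng):
    """Planting a two-latency mixture into 61-channel pink noise, the full
    pipeline recovers both latencies within 2 ms."""
    fs, trial_s, n_trials, n_ch = 500.0, 6.3, 12, 61
    sim = alpc.synthesize(alpc.example_recipe(1, snr_db=None,
                                              duration_s=trial_s, fs_hz=fs))
    n = int(trial_s * fs)
    # CAR removes the mean loading, so the analysed channel must carry the
    # response more strongly than the montage average
    gains = rng.uniform(0.2, 0.8, size=n_ch)
    gains[0] = 1.5
    data = np.empty((n_trials, n_ch, n))
    for tr in range(n_trials):
        for ch in range(n_ch):
            data[tr, ch] = 2.0 * _pink_noise(rng, n, fs) + gains[ch] * sim.signal
    data[3] *= 8.0  # one artifact trial

    rec = _recording(data, fs=fs)
    rec = rereference_car(rec)
    rec = zero_phase_filter(rec)
    rec = reject_bad_trials(rec)
    assert 3 in rec.excluded_trials

    meas, table = extract_trial_phases(rec, sim.all_frequencies,
                                       method="avg_eeg", channel=0)
    # seed with a pair from one generator (as with the strongest beat pair
    # in practice): a single-frequency start can pair with an arbitrary
    # candidate at step 1, since two phases are fit exactly by some delay
    results = alpc.extract_all_latencies(
        meas,
        alpc.SfsConfig(delta_t_ms=300.0),
        weights=alpc.lci(table),
        first_start=(38.0, 42.0),
    )
    lats = sorted(r.estimate.latency_ms for r in results[:2])
    assert lats[0] == pytest.approx(21.0, abs=2.0)
    assert lats[1] == pytest.approx(51.0, abs=2.0)
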