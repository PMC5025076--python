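"""Filtering, montage selection and epoching behavior."""
import numpy as np
import pytest

from icabci.preprocessing import (EIGHT_CHANNEL_SCHEME, NINE_CHANNEL_SCHEME,
                                  ChannelScheme, InvalidParameterError,
                                  ChannelNotFoundError, MultichannelRecording,
                                  bandpass_filter, epoch_trials, notch_filter,
                                  select_channels)

FS = 250.0


def sine_rec(freq, dur=10.0, fs=FS, n_ch=2):
    t = np.arange(int(dur * fs)) / fs
    x = np.tile(np.sin(2 * np.pi * freq * t), (n_ch, 1))
    return MultichannelRecording(x, fs, [f"ch{i}" for i in range(n_ch)])


def mid_rms(rec):
    """RMS over the middle half of the recording (edge-effect free)."""
    n = rec.n_samples
    return float(np.sqrt(np.mean(rec.samples[:, n // 4: 3 * n // 4] ** 2)))


@pytest.mark.parametrize("freq,passes", [(12.0, True), (4.0, False)])
def test_bandpass_pass_and_stop(freq, passes):
    """8-30 Hz band-pass keeps a 12 Hz tone within 5% and attenuates a
    4 Hz tone by at least 40 dB."""
    rec = sine_rec(freq)
    out = bandpass_filter(rec, 8.0, 30.0)
    ratio = mid_rms(out) / mid_rms(rec)
    if passes:
        assert abs(ratio - 1.0) < 0.05
    else:
        assert 20 * np.log10(ratio) < -40.0


def test_notch_attenuates_line_frequency_only():
    """The 50 Hz notch removes >= 30 dB at 50 Hz and leaves 12 Hz intact."""
    out50 = notch_filter(sine_rec(50.0), 50.0)
    out12 = notch_filter(sine_rec(12.0), 50.0)
    assert 20 * np.log10(mid_rms(out50) / mid_rms(sine_rec(50.0))) < -30.0
    assert abs(mid_rms(out12) / mid_rms(sine_rec(12.0)) - 1.0) < 0.05


def test_notch_of_zero_signal_is_zero():
    rec = MultichannelRecording(np.zeros((2, 2500)), FS, ["a", "b"])
    assert np.allclose(notch_filter(rec, 50.0).samples, 0.0)


def test_zero_phase_no_lag():
    """Input/output cross-correlation of the band-pass peaks at lag 0."""
    rng = np.random.default_rng(0)
    rec = MultichannelRecording(rng.standard_normal((1, 5000)), FS, ["a"])
    out = bandpass_filter(rec, 8.0, 30.0)
    x = bandpass_filter(out, 8.0, 30.0).samples[0]  # compare within passband
    y = out.samples[0]
    xc = np.correlate(x - x.mean(), y - y.mean(), mode="full")
    assert abs(int(np.argmax(xc)) - (len(x) - 1)) == 0


def test_filtering_is_linear():
    rng = np.random.default_rng(1)
    x = rng.standard_normal((2, 3000))
    y = rng.standard_normal((2, 3000))
    fa = bandpass_filter(MultichannelRecording(x, FS, ["a", "b"]), 8, 30).samples
    fb = bandpass_filter(MultichannelRecording(y, FS, ["a", "b"]), 8, 30).samples
    fab = bandpass_filter(
        MultichannelRecording(2.0 * x - 0.5 * y, FS, ["a", "b"]), 8, 30).samples
    assert np.allclose(fab, 2.0 * fa - 0.5 * fb, atol=1e-9)


@pytest.mark.parametrize("low,high", [(0, 30), (8, 130), (30, 8), (-1, 20)])
def test_invalid_band_edges_raise(low, high):
    rec = sine_rec(12.0)
    with pytest.raises(InvalidParameterError):
        bandpass_filter(rec, low, high)


def test_select_channels_nine_scheme_order():
    """A 14-channel recording reduces to the 9-channel montage in order."""
    labels14 = ["FP1", "FP2", "F3", "F4", "FC3", "FCz", "FC4", "C3", "Cz",
                "C4", "CP3", "CPz", "CP4", "Pz"]
    rng = np.random.default_rng(2)
    rec = MultichannelRecording(rng.standard_normal((14, 1000)), FS, labels14)
    out = select_channels(rec, NINE_CHANNEL_SCHEME)
    assert out.channel_labels == ["FC3", "FCz", "FC4", "C3", "Cz", "C4",
                                  "CP3", "CPz", "CP4"]
    for i, lab in enumerate(out.channel_labels):
        src = labels14.index(lab)
        assert np.array_equal(out.samples[i], rec.samples[src])


def test_select_channels_identity_and_missing():
    rng = np.random.default_rng(3)
    rec = MultichannelRecording(rng.standard_normal((8, 100)), FS,
                                list(EIGHT_CHANNEL_SCHEME.labels))
    same = select_channels(rec, EIGHT_CHANNEL_SCHEME)
    assert np.array_equal(same.samples, rec.samples)
    with pytest.raises(ChannelNotFoundError):
        select_channels(rec, ChannelScheme("bogus", ("FP1", "XX")))


def test_epoch_lengths_and_labels():
    """0.5-5 s at 250 Hz gives 1125-sample trials; 0-10 s gives 2500."""
    rng = np.random.default_rng(4)
    n_trial = 2500
    rec = MultichannelRecording(rng.standard_normal((2, 3 * n_trial)), FS,
                                ["a", "b"],
                                events=[(0, 1), (n_trial, 2), (2 * n_trial, 3)])
    ts = epoch_trials(rec, (0.5, 5.0))
    assert all(t.shape == (2, 1125) for t in ts.trials)
    assert list(ts.labels) == [1, 2, 3]
    assert list(ts.trial_index) == [1, 2, 3]
    full = epoch_trials(rec, (0.0, 10.0))
    assert full.trials[0].shape == (2, 2500)


def test_epoch_no_events_empty():
    rec = MultichannelRecording(np.zeros((2, 1000)), FS, ["a", "b"])
    assert len(epoch_trials(rec, (0.0, 1.0))) == 0


def test_epoch_window_exceeding_spacing_raises():
    rec = MultichannelRecording(np.zeros((1, 1000)), FS, ["a"],
                                events=[(0, 1), (250, 2)])
    with pytest.raises(InvalidParameterError):
        epoch_trials(rec, (0.0, 2.0))


def test_epoch_concatenation_reconstructs_run():
    """Contiguous zero-overlap epochs concatenate back to the raw samples."""
    rng = np.random.default_rng(5)
    n_trial, k = 500, 4
    x = rng.standard_normal((3, n_trial * k))
    rec = MultichannelRecording(x, FS, ["a", "b", "c"],
                                events=[(i * n_trial, 1 + i % 3) for i in range(k)])
    ts = epoch_trials(rec, (0.0, n_trial / FS))
    assert np.array_equal(np.concatenate(ts.trials, axis=1), x)


def test_event_validation():
    with pytest.raises(InvalidParameterError):
        MultichannelRecording(np.zeros((1, 100)), FS, ["a"],
                              events=[(50, 1), (10, 2)])
    with pytest.raises(InvalidParameterError):
        MultichannelRecording(np.zeros((1, 100)), FS, ["a"], events=[(10, 7)])
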