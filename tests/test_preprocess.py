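import numpy as np
import pytest

from erspconn import preprocess, synth
from erspconn.types import EpochSet, RawRecording


def make_raw(n_channels=4, n_samples=10000, fs=250.0, seed=0, labels=None):
    rng = np.random.default_rng(seed)
    if labels is None:
        labels = [f"ch{i}" for i in range(n_channels - 2)] + ["M1", "M2"]
    return RawRecording(
        rng.standard_normal((n_channels, n_samples)), fs, labels
    )


class TestDetrendAndReference:
    def test_linear_ramp_removed(self):
        raw = make_raw()
        raw.data[0] += 0.05 * np.arange(raw.n_samples)
        out = preprocess.detrend_and_reference(raw)
        slope = np.polyfit(np.arange(out.n_samples), out.data[0], 1)[0]
        assert abs(slope) < 1e-9

    def test_mastoid_mean_zero(self):
        raw = make_raw()
        out = preprocess.detrend_and_reference(raw)
        m1 = out.channel_index("M1")
        m2 = out.channel_index("M2")
        assert np.allclose(0.5 * (out.data[m1] + out.data[m2]), 0.0, atol=1e-12)

    def test_constant_channel_becomes_zero(self):
        raw = make_raw()
        raw.data[0] = 7.5
        raw.data[-2:] = 0.0  # quiet mastoids so referencing adds nothing back
        out = preprocess.detrend_and_reference(raw)
        assert np.allclose(out.data[0], 0.0, atol=1e-9)

    def test_missing_mastoid_rejected(self):
        raw = make_raw(labels=["a", "b", "c", "d"])
        with pytest.raises(ValueError, match="mastoid"):
            preprocess.detrend_and_reference(raw)


class TestBandpassZeroPhase:
    def test_60hz_attenuated(self):
        fs = 250.0
        t = np.arange(30 * fs) / fs
        raw = RawRecording(np.sin(2 * np.pi * 60 * t)[None, :], fs, ["a"])
        out = preprocess.bandpass_zero_phase(raw)
        mid = slice(2000, -2000)  # skip filter edge transients
        rms_in = np.sqrt((raw.data[0, mid] ** 2).mean())
        rms_out = np.sqrt((out.data[0, mid] ** 2).mean())
        assert 20 * np.log10(rms_in / rms_out) >= 20

    def test_10hz_passband_gain_and_zero_lag(self):
        fs = 250.0
        t = np.arange(30 * fs) / fs
        raw = RawRecording(np.sin(2 * np.pi * 10 * t)[None, :], fs, ["a"])
        out = preprocess.bandpass_zero_phase(raw)
        mid = slice(2000, -2000)
        gain = np.sqrt((out.data[0, mid] ** 2).mean() / (raw.data[0, mid] ** 2).mean())
        assert abs(20 * np.log10(gain)) < 0.5
        xc = np.correlate(out.data[0, mid], raw.data[0, mid], "full")
        lag = np.argmax(xc) - (len(raw.data[0, mid]) - 1)
        assert lag == 0

    def test_zero_in_zero_out(self):
        raw = RawRecording(np.zeros((2, 8000)), 250.0, ["a", "b"])
        out = preprocess.bandpass_zero_phase(raw)
        assert np.allclose(out.data, 0.0)

    def test_passband_idempotence(self):
        fs = 250.0
        t = np.arange(30 * fs) / fs
        raw = RawRecording(np.sin(2 * np.pi * 10 * t)[None, :], fs, ["a"])
        once = preprocess.bandpass_zero_phase(raw)
        twice = preprocess.bandpass_zero_phase(once)
        mid = slice(2000, -2000)
        ratio = np.sqrt(
            (twice.data[0, mid] ** 2).mean() / (once.data[0, mid] ** 2).mean()
        )
        assert abs(20 * np.log10(ratio)) < 1.0

    def test_invalid_corners_rejected(self):
        raw = make_raw()
        with pytest.raises(ValueError, match="fs/2"):
            preprocess.bandpass_zero_phase(raw, 0.5, 200.0)
        with pytest.raises(ValueError):
            preprocess.bandpass_zero_phase(raw, 48.0, 0.5)


class TestSegment:
    def test_epoch_length_and_time_axis(self):
        fs = 250.0
        raw = make_raw(n_samples=5000, fs=fs)
        raw.events = [(2500, "go")]
        ep = preprocess.segment(raw, {"go": "supportive"})
        assert ep.n_samples == 1500
        assert ep.time_ms[0] == -4000.0
        assert ep.time_ms[-1] == pytest.approx(2000.0 - 1000.0 / fs)

    def test_marker_too_close_to_edge_skipped(self):
        raw = make_raw(n_samples=5000)
        raw.events = [(100, "go"), (2500, "go")]
        with pytest.warns(UserWarning, match="skipped 1"):
            ep = preprocess.segment(raw, {"go": "supportive"})
        assert ep.n_trials == 1

    def test_no_markers_gives_empty_epochs(self):
        raw = make_raw(n_samples=5000)
        ep = preprocess.segment(raw, {"go": "supportive"})
        assert ep.n_trials == 0

    def test_epochs_equal_raw_slices_exactly(self):
        raw = make_raw(n_samples=5000)
        raw.events = [(2500, "go")]
        ep = preprocess.segment(raw, {"go": "supportive"})
        assert np.array_equal(ep.data[0], raw.data[:, 1500:3000])


class TestRejectAmplitude:
    @pytest.fixture()
    def frontal_epochs(self, noise_epochs):
        return noise_epochs.copy()

    def test_blink_rejected(self, frontal_epochs):
        ch = frontal_epochs.channel_index("AFp1")
        sl = frontal_epochs.time_slice(0.0, 400.0)
        frontal_epochs.data[4, ch, sl] += 250.0 * np.hanning(sl.stop - sl.start)
        out = preprocess.reject_amplitude(frontal_epochs)
        assert not out.kept_mask[4]

    def test_199uv_kept(self, small_epochs):
        ep = small_epochs.with_data(np.zeros_like(small_epochs.data))
        ep.data[0, 0, 250] = 199.0
        out = preprocess.reject_amplitude(ep, channels=["a"])
        assert out.kept_mask[0]
        ep.data[0, 0, 250] = 201.0
        out = preprocess.reject_amplitude(ep, channels=["a"])
        assert not out.kept_mask[0]

    def test_non_frontal_deflection_kept(self, frontal_epochs):
        ch = frontal_epochs.channel_index("P3")
        sl = frontal_epochs.time_slice(0.0, 400.0)
        frontal_epochs.data[4, ch, sl] += 250.0 * np.hanning(sl.stop - sl.start)
        out = preprocess.reject_amplitude(frontal_epochs)
        assert out.kept_mask[4]

    def test_data_never_mutated(self, frontal_epochs):
        before = frontal_epochs.data.copy()
        preprocess.reject_amplitude(frontal_epochs)
        assert np.array_equal(frontal_epochs.data, before)

    def test_empty_group_rejected(self, frontal_epochs):
        with pytest.raises(ValueError, match="empty"):
            preprocess.reject_amplitude(frontal_epochs, channels=[])

    def test_peak_to_peak_mode(self, small_epochs):
        ep = small_epochs.with_data(np.zeros_like(small_epochs.data))
        ep.data[0, 0, 100] = 110.0
        ep.data[0, 0, 200] = -110.0
        kept_md = preprocess.reject_amplitude(ep, channels=["a"]).kept_mask[0]
        kept_pp = preprocess.reject_amplitude(
            ep, channels=["a"], mode="peak_to_peak"
        ).kept_mask[0]
        assert kept_md and not kept_pp


def mixture_epochs(seed=0, n_trials=30, n_samp=500, fs=250.0):
    """3-channel mixture of a blink-like source and two Laplace sources."""
    rng = np.random.default_rng(seed)
    n = n_trials * n_samp
    blink = np.zeros(n)
    for pos in rng.integers(100, n - 100, 40):
        blink[pos - 50 : pos + 50] += np.hanning(100) * rng.uniform(5, 10)
    sources = np.vstack([blink, rng.laplace(size=n), rng.laplace(size=n)])
    mixing = rng.standard_normal((3, 3)) + 2 * np.eye(3)
    data = (mixing @ sources).reshape(3, n_trials, n_samp).transpose(1, 0, 2)
    time_ms = np.arange(n_samp) * (1000.0 / fs)
    epochs = EpochSet(
        data, time_ms, ["x", "y", "z"],
        np.array(["supportive"] * n_trials), fs,
    )
    return epochs, sources


class TestIca:
    def test_blink_source_recovered(self):
        epochs, sources = mixture_epochs(seed=1)
        model = preprocess.ica_fit(epochs, seed=2)
        recovered = model.sources(epochs).transpose(1, 0, 2).reshape(3, -1)
        corr = np.abs(np.corrcoef(np.vstack([sources[:1], recovered]))[0, 1:])
        assert corr.max() > 0.9

    def test_no_flags_reconstruction_identity(self):
        epochs, _ = mixture_epochs(seed=3)
        model = preprocess.ica_fit(epochs, seed=4)
        out = preprocess.ica_remove(model, epochs)
        assert np.abs(out.data - epochs.data).max() < 1e-6

    def test_removing_component_changes_data(self):
        epochs, _ = mixture_epochs(seed=5)
        model = preprocess.ica_fit(epochs, seed=6)
        model.component_flags[0] = "manual"
        out = preprocess.ica_remove(model, epochs)
        assert np.abs(out.data - epochs.data).max() > 1e-3

    def test_rank_deficient_rejected(self):
        epochs, _ = mixture_epochs(seed=7)
        epochs.data[:, 2, :] = epochs.data[:, 0, :]  # duplicate channel
        with pytest.raises(ValueError, match="rank"):
            preprocess.ica_fit(epochs)

    def test_too_few_samples_rejected(self):
        rng = np.random.default_rng(8)
        epochs = EpochSet(
            rng.standard_normal((1, 3, 100)),
            np.arange(100) * 4.0,
            ["x", "y", "z"],
            np.array(["supportive"]),
            250.0,
        )
        with pytest.raises(ValueError, match="too few samples"):
            preprocess.ica_fit(epochs)

    def test_flag_ocular_component(self, montage):
        # blink-like source projected onto the frontal group only
        rng = np.random.default_rng(9)
        n_trials, n_samp, fs = 45, 500, 250.0
        n = n_trials * n_samp
        blink = np.zeros(n)
        for pos in rng.integers(100, n - 100, 60):
            blink[pos - 60 : pos + 60] += np.hanning(120) * rng.uniform(20, 40)
        data = rng.standard_normal((32, n))
        frontal = [montage.index(lb) for lb in montage.groups["frontal"]]
        for i in frontal:
            data[i] += blink
        epochs = EpochSet(
            data.reshape(32, n_trials, n_samp).transpose(1, 0, 2),
            np.arange(n_samp) * (1000.0 / fs),
            list(montage.labels),
            np.array(["supportive"] * n_trials),
            fs,
        )
        model = preprocess.ica_fit(epochs, seed=10, max_iter=200)
        flagged = preprocess.ica_flag(model, epochs, montage)
        assert "ocular" in [f for f in flagged.component_flags if f]
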