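import numpy as np
import pytest
from scipy import signal

from erspconn import clusterstats, connectivity, synth


def band_power_db_change(before, after, channel, band, window, fs):
    """Oracle: dB change of band-passed power in a window, before vs after."""
    sos = signal.butter(4, list(band), btype="bandpass", fs=fs, output="sos")
    sl = before.time_slice(*window)
    ci = before.channel_index(channel)
    b0 = signal.sosfiltfilt(sos, before.data[:, ci], axis=-1)[:, sl]
    b1 = signal.sosfiltfilt(sos, after.data[:, ci], axis=-1)[:, sl]
    return 10.0 * np.log10((b1**2).mean() / (b0**2).mean())


class TestMontage:
    def test_study32_labels(self, montage):
        assert len(montage.labels) == 32
        assert "POO1" in montage.labels and "POO2" in montage.labels
        for lb in ("AFp1", "AFp2", "AFF5h", "AFF6h"):
            assert lb in montage.groups["frontal"]
        assert montage.groups["mastoids"] == ["M1", "M2"]

    def test_positions_pairwise_distinct(self, montage):
        d = np.linalg.norm(
            montage.pos2d[:, None] - montage.pos2d[None, :], axis=-1
        )
        np.fill_diagonal(d, np.inf)
        assert (d > 0).all()

    def test_neighbor_graph_symmetric(self, montage):
        graph = clusterstats.build_neighbors(montage)
        assert np.array_equal(graph.adjacency, graph.adjacency.T)

    def test_unknown_preset_names_available(self):
        with pytest.raises(ValueError, match="study32"):
            synth.make_montage("nope")

    def test_group_labels_validated(self):
        with pytest.raises(ValueError, match="unknown labels"):
            synth.Montage(["a", "b"], [[0, 0], [1, 0]], {"g": ["zz"]})


class TestSimulateDataset:
    def test_shapes(self):
        cfg = synth.SimulationConfig(
            fs=250.0, n_subjects=1, n_trials_per_condition=10, seed=0
        )
        datasets, ledger = synth.simulate_dataset(cfg)
        assert datasets[0].data.shape == (20, 32, 1500)
        assert ledger["effects"] == []

    def test_determinism(self):
        cfg = synth.SimulationConfig(
            fs=250.0, n_subjects=2, n_trials_per_condition=5, seed=42
        )
        a, _ = synth.simulate_dataset(cfg)
        b, _ = synth.simulate_dataset(cfg)
        for ea, eb in zip(a, b):
            assert np.array_equal(ea.data, eb.data)

    def test_null_band_power_flat(self, noise_epochs):
        # no effects: adaptation-window band power ≈ rest-window band power
        # (Welch-PSD oracle integrated over 8-14 Hz)
        ep = noise_epochs
        x = ep.data[:, ep.channel_index("C3")]

        def band_power(window):
            seg = x[:, ep.time_slice(*window)]
            freqs, psd = signal.welch(seg, fs=ep.fs, nperseg=250, axis=-1)
            sel = (freqs >= 8) & (freqs <= 14)
            return psd[:, sel].mean()

        ratio = band_power((1000, 2000)) / band_power((-4000, -2000))
        assert abs(10 * np.log10(ratio)) < 0.5

    def test_unknown_effect_channel_rejected(self):
        eff = synth.EffectSpec(
            "power_modulation", ["nope"], band=(8.0, 14.0),
            window=(1000.0, 2000.0), magnitude=-3.0,
        )
        cfg = synth.SimulationConfig(
            n_subjects=1, n_trials_per_condition=2, effects=[eff], seed=0
        )
        with pytest.raises(ValueError, match="not in montage"):
            synth.simulate_dataset(cfg)

    def test_ledger_records_every_effect(self):
        effs = [
            synth.EffectSpec(
                "power_modulation", ["C3"], band=(8.0, 14.0),
                window=(1000.0, 2000.0), magnitude=-3.0,
            ),
            synth.EffectSpec(
                "amplitude_artifact", ["AFp1"], window=(0.0, 400.0),
                magnitude=250.0, trials=[1],
            ),
        ]
        cfg = synth.SimulationConfig(
            n_subjects=1, n_trials_per_condition=3, effects=effs, seed=0
        )
        _, ledger = synth.simulate_dataset(cfg)
        assert len(ledger["effects"]) == 2
        assert ledger["effects"][0]["magnitude"] == -3.0
        assert ledger["artifact_trials"]["0"] == [1]


class TestPowerModulation:
    def test_minus_3db_measured(self, noise_epochs):
        channels = ["C3", "C4", "P3", "P4"]
        eff = synth.EffectSpec(
            "power_modulation", channels, band=(8.0, 14.0),
            window=(1000.0, 2000.0), magnitude=-3.0,
        )
        out = synth.inject_power_modulation(noise_epochs, eff)
        change = band_power_db_change(
            noise_epochs, out, "C3", (8.0, 14.0), (1000.0, 2000.0), noise_epochs.fs
        )
        assert change == pytest.approx(-3.0, abs=0.7)

    def test_zero_magnitude_is_identity(self, noise_epochs):
        eff = synth.EffectSpec(
            "power_modulation", ["C3"], band=(8.0, 14.0),
            window=(1000.0, 2000.0), magnitude=0.0,
        )
        out = synth.inject_power_modulation(noise_epochs, eff)
        assert np.array_equal(out.data, noise_epochs.data)

    def test_rest_window_untouched(self, noise_epochs):
        eff = synth.EffectSpec(
            "power_modulation", ["C3"], band=(8.0, 14.0),
            window=(1000.0, 2000.0), magnitude=-3.0,
        )
        out = synth.inject_power_modulation(noise_epochs, eff)
        change = band_power_db_change(
            noise_epochs, out, "C3", (8.0, 14.0), (-4000.0, -2000.0), noise_epochs.fs
        )
        assert abs(change) < 0.5

    def test_other_channels_untouched(self, noise_epochs):
        eff = synth.EffectSpec(
            "power_modulation", ["C3"], band=(8.0, 14.0),
            window=(1000.0, 2000.0), magnitude=-3.0,
        )
        out = synth.inject_power_modulation(noise_epochs, eff)
        other = [i for i, lb in enumerate(noise_epochs.labels) if lb != "C3"]
        assert np.array_equal(out.data[:, other], noise_epochs.data[:, other])

    def test_band_above_nyquist_rejected(self, noise_epochs):
        eff = synth.EffectSpec(
            "power_modulation", ["C3"], band=(100.0, 140.0),
            window=(1000.0, 2000.0), magnitude=-3.0,
        )
        with pytest.raises(ValueError, match="Nyquist"):
            synth.inject_power_modulation(noise_epochs, eff)


class TestLaggedCoupling:
    def test_quarter_cycle_lag_gives_cicoh(self, noise_epochs):
        eff = synth.EffectSpec(
            "lagged_coupling", ["POO1", "C3"], band=(8.0, 12.0),
            magnitude=0.8, phase_lag=np.pi / 2,
        )
        out = synth.inject_lagged_coupling(noise_epochs, eff)
        pair = [(out.channel_index("POO1"), out.channel_index("C3"))]
        cs = connectivity.trial_coherency(out, pair, (-3000.0, -2000.0))
        f10 = np.argmin(np.abs(cs.freqs - 10.0))
        assert cs.cicoh[:, 0, f10].mean() > 0.3

    def test_zero_lag_gives_no_cicoh(self):
        cfg = synth.SimulationConfig(
            fs=250.0, n_subjects=1, n_trials_per_condition=250, seed=11
        )
        (ep,), _ = synth.simulate_dataset(cfg)
        eff = synth.EffectSpec(
            "lagged_coupling", ["POO1", "C3"], band=(8.0, 12.0),
            magnitude=0.8, phase_lag=0.0,
        )
        out = synth.inject_lagged_coupling(ep, eff)
        pair = [(out.channel_index("POO1"), out.channel_index("C3"))]
        cs = connectivity.trial_coherency(out, pair, (-3000.0, -2000.0))
        f10 = np.argmin(np.abs(cs.freqs - 10.0))
        assert abs(cs.cicoh[:, 0, f10].mean()) < 0.05

    def test_adaptation_only_coupling_gives_positive_er_cicoh(self, noise_epochs):
        eff = synth.EffectSpec(
            "lagged_coupling", ["POO1", "C3", "CP3"], band=(35.0, 45.0),
            window=(1000.0, 2000.0), magnitude=0.8, phase_lag=np.pi / 2,
        )
        out = synth.inject_lagged_coupling(noise_epochs, eff)
        emap = connectivity.er_cicoh(out)
        gamma = list(emap.bands).index("gamma")
        targets = [out.channel_index("C3"), out.channel_index("CP3")]
        untouched = out.channel_index("F7")
        assert emap.values[targets, gamma].min() > 0.2
        assert abs(emap.values[untouched, gamma]) < 0.2

    def test_phase_lag_without_band_rejected(self):
        with pytest.raises(ValueError, match="band"):
            synth.EffectSpec(
                "lagged_coupling", ["a", "b"], magnitude=0.5, phase_lag=1.0
            )


class TestMixing:
    def test_identity(self, noise_epochs):
        out = synth.apply_mixing(noise_epochs, np.eye(32))
        assert np.allclose(out.data, noise_epochs.data)

    def test_wrong_size_rejected(self, noise_epochs):
        with pytest.raises(ValueError, match="does not match"):
            synth.apply_mixing(noise_epochs, np.eye(5))
        with pytest.raises(ValueError, match="square"):
            synth.apply_mixing(noise_epochs, np.ones((32, 5)))

    def test_rank_preserved_under_invertible_mixing(self, small_epochs):
        rng = np.random.default_rng(3)
        m = rng.standard_normal((3, 3)) + 3 * np.eye(3)
        out = synth.apply_mixing(small_epochs, m)
        flat_in = small_epochs.data.transpose(1, 0, 2).reshape(3, -1)
        flat_out = out.data.transpose(1, 0, 2).reshape(3, -1)
        assert np.linalg.matrix_rank(flat_out) == np.linalg.matrix_rank(flat_in)

    def test_zero_lag_mixture_coh_without_cicoh(self):
        # two independent sources leaked instantaneously into both channels
        cfg = synth.SimulationConfig(
            fs=250.0, n_subjects=1, n_trials_per_condition=250, seed=21
        )
        (ep,), _ = synth.simulate_dataset(cfg)
        m = np.eye(32)
        i, j = ep.channel_index("C3"), ep.channel_index("C4")
        m[i, j] = 0.6
        m[j, i] = 0.6
        out = synth.apply_mixing(ep, m)
        cs = connectivity.trial_coherency(out, [(i, j)], (-3000.0, -2000.0))
        f10 = np.argmin(np.abs(cs.freqs - 10.0))
        assert np.abs(cs.coh[:, 0, f10]).mean() > 0.3
        assert abs(cs.cicoh[:, 0, f10].mean()) < 0.05


class TestAmplitudeArtifact:
    def test_contaminated_trials_rejected(self, noise_epochs):
        from erspconn import preprocess

        eff = synth.EffectSpec(
            "amplitude_artifact", ["AFp1"], window=(0.0, 400.0),
            magnitude=250.0, trials=[3, 7],
        )
        out, hit = synth.inject_amplitude_artifact(noise_epochs, eff)
        assert hit == [3, 7]
        rejected = preprocess.reject_amplitude(out)
        assert sorted(np.nonzero(~rejected.kept_mask)[0]) == [3, 7]

    def test_no_artifacts_is_identity(self, noise_epochs):
        eff = synth.EffectSpec(
            "amplitude_artifact", ["AFp1"], window=(0.0, 400.0),
            magnitude=250.0, trials=[],
        )
        out, hit = synth.inject_amplitude_artifact(noise_epochs, eff)
        assert hit == []
        assert np.array_equal(out.data, noise_epochs.data)

    def test_non_frontal_artifact_not_rejected(self, noise_epochs):
        from erspconn import preprocess

        eff = synth.EffectSpec(
            "amplitude_artifact", ["P3"], window=(0.0, 400.0),
            magnitude=250.0, trials=[2],
        )
        out, _ = synth.inject_amplitude_artifact(noise_epochs, eff)
        rejected = preprocess.reject_amplitude(out)
        assert rejected.kept_mask.all()


class TestEpochsToRaw:
    def test_round_trip_via_segmentation(self):
        from erspconn import preprocess

        cfg = synth.SimulationConfig(
            fs=250.0, n_subjects=1, n_trials_per_condition=3, seed=5
        )
        (ep,), _ = synth.simulate_dataset(cfg)
        raw = synth.epochs_to_raw(ep)
        seg = preprocess.segment(
            raw, {"supportive": "supportive", "impeding": "impeding"}
        )
        assert seg.data.shape == ep.data.shape
        assert np.allclose(seg.data, ep.data)
        assert (seg.condition == ep.condition).all()
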