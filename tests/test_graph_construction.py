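"""PLV adjacency and filter-bank band-power features against independent
oracles: analytic-signal identities, Monte Carlo phase statistics, recomputed
moments, FFT/Parseval energy accounting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sfegat.graph_construction import (
    FilterBankSpec,
    build_graph,
    build_graph_dataset,
    compute_plv_matrix,
    filter_bank,
    instantaneous_phase,
    standardize_plv,
    threshold_adjacency,
    welch_band_power,
)
from sfegat.io_eeg import EpochedTrial

FS = 250.0


def sine_trial(freqs, fs=FS, t_s=4.0, phases=None, label=0):
    t = np.arange(int(t_s * fs)) / fs
    phases = phases or [0.0] * len(freqs)
    data = np.stack([np.cos(2 * np.pi * f * t + p) for f, p in zip(freqs, phases)])
    return EpochedTrial(data=data, label=label, fs=fs)


class TestInstantaneousPhase:
    def test_pure_tone_phase_velocity(self):
        t = np.arange(250) / FS
        phase = instantaneous_phase(np.cos(2 * np.pi * 10 * t))
        dphi = np.diff(np.unwrap(phase))[25:-25]  # away from edges
        np.testing.assert_allclose(dphi, 2 * np.pi * 10 / FS, rtol=1e-3)

    def test_quadrature_offset(self):
        t = np.arange(1000) / FS
        ps = instantaneous_phase(np.sin(2 * np.pi * 12 * t))
        pc = instantaneous_phase(np.cos(2 * np.pi * 12 * t))
        mid = slice(200, 800)
        diff = np.angle(np.exp(1j * (pc[mid] - ps[mid])))
        np.testing.assert_allclose(diff, np.pi / 2, atol=1e-2)

    def test_white_noise_phase_in_range(self, rng):
        phase = instantaneous_phase(rng.normal(size=2000))
        assert np.all(np.isfinite(phase))
        assert phase.min() > -np.pi - 1e-12 and phase.max() <= np.pi + 1e-12

    def test_constant_signal_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            instantaneous_phase(np.ones(100))

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="4 samples"):
            instantaneous_phase(np.array([0.0, 1.0]))


class TestPLV:
    def test_identical_channels_lock_perfectly(self, rng):
        x = rng.normal(size=1000)
        trial = EpochedTrial(np.stack([x, x]), label=0, fs=FS)
        plv = compute_plv_matrix(trial, band=None)
        np.testing.assert_allclose(plv, 1.0, atol=1e-12)

    def test_constant_phase_offset_locks_perfectly(self):
        trial = sine_trial([10.0, 10.0], phases=[0.0, 1.2])
        plv = compute_plv_matrix(trial, band=None)
        assert plv[0, 1] > 0.999

    def test_independent_phases_near_zero(self, rng):
        # Monte Carlo oracle: mean unit phasor of T i.i.d. phases is
        # O(1/sqrt(T)); fully independent per-sample phases realise it.
        t_len = 4000
        phases = rng.uniform(-np.pi, np.pi, size=(2, t_len))
        plv = abs(np.mean(np.exp(1j * (phases[0] - phases[1]))))
        assert plv <= 3 / np.sqrt(t_len)

    def test_matrix_contract(self, rng):
        trial = EpochedTrial(rng.normal(size=(6, 1000)), label=0, fs=FS)
        plv = compute_plv_matrix(trial)
        np.testing.assert_allclose(plv, plv.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(plv), 1.0, atol=1e-12)
        assert plv.min() >= 0.0 and plv.max() <= 1.0 + 1e-12

    def test_amplitude_scaling_invariance(self, rng):
        """PLV is a phase-only statistic: scaling a channel leaves it unchanged."""
        data = rng.normal(size=(4, 1000))
        t1 = EpochedTrial(data.copy(), label=0, fs=FS)
        scaled = data.copy()
        scaled[1] *= 7.3
        t2 = EpochedTrial(scaled, label=0, fs=FS)
        np.testing.assert_allclose(
            compute_plv_matrix(t1, band=None),
            compute_plv_matrix(t2, band=None),
            atol=1e-10,
        )

    def test_brute_force_oracle(self, rng):
        """Matrix path agrees with an explicit double loop over pairs."""
        trial = EpochedTrial(rng.normal(size=(5, 800)), label=0, fs=FS)
        plv = compute_plv_matrix(trial, band=None)
        phases = instantaneous_phase(trial.data)
        for i in range(5):
            for j in range(5):
                expected = abs(np.mean(np.exp(1j * (phases[i] - phases[j]))))
                assert abs(plv[i, j] - expected) < 1e-9


class TestStandardizeThreshold:
    def test_standardization_moment_oracle(self, rng):
        p = rng.random((7, 7))
        p = (p + p.T) / 2
        np.fill_diagonal(p, 1.0)
        z = standardize_plv(p)
        np.testing.assert_allclose(z.mean(), 0.0, atol=1e-7)
        np.testing.assert_allclose(z.std(), 1.0, atol=1e-7)
        np.testing.assert_allclose(z, z.T)

    def test_constant_matrix_guarded_by_eps(self):
        z = standardize_plv(np.full((4, 4), 0.7))
        assert np.all(np.isfinite(z))
        np.testing.assert_allclose(z, 0.0, atol=1e-12)

    def test_moments_use_all_entries_including_diagonal(self, rng):
        p = rng.random((5, 5))
        z = standardize_plv(p)
        mu, sigma = p.mean(), p.std()
        np.testing.assert_allclose(z, (p - mu) / (sigma + 1e-8), atol=1e-12)

    def test_threshold_enumeration_oracle(self):
        std = np.array(
            [[9.0, -0.5, 0.2], [-0.5, 9.0, 1.1], [0.2, 1.1, 9.0]]
        )
        adj = threshold_adjacency(std, tau=0.0)
        assert adj[0, 1] == 0.0  # below threshold
        assert adj[0, 2] == 0.2 and adj[1, 2] == 1.1  # retained with weight
        np.testing.assert_array_equal(np.diag(adj), 0.0)  # diagonal zeroed first

    def test_extreme_thresholds(self, rng):
        std = rng.normal(size=(6, 6))
        std = (std + std.T) / 2
        all_kept = threshold_adjacency(std, tau=-np.inf)
        off_diag = ~np.eye(6, dtype=bool)
        assert np.all(all_kept[off_diag] == std[off_diag])
        assert np.all(threshold_adjacency(std, tau=np.inf) == 0.0)

    @given(tau_pair=st.tuples(st.floats(-2, 2), st.floats(-2, 2)))
    @settings(max_examples=25, deadline=None, derandomize=True, database=None)
    def test_edge_count_monotone_in_threshold(self, tau_pair):
        rng = np.random.default_rng(7)
        std = rng.normal(size=(8, 8))
        std = (std + std.T) / 2
        lo, hi = sorted(tau_pair)
        n_lo = np.count_nonzero(threshold_adjacency(std, tau=lo))
        n_hi = np.count_nonzero(threshold_adjacency(std, tau=hi))
        assert n_hi <= n_lo


class TestFilterBank:
    def test_default_spec_has_eight_bands(self):
        assert FilterBankSpec().n_bands == 8
        assert FilterBankSpec().bands[0] == (8.0, 12.0)
        assert FilterBankSpec().bands[-1] == (36.0, 40.0)

    def test_tone_lands_in_its_band(self):
        """FFT amplitude oracle: a 10 Hz tone passes the 8-12 band and is
        attenuated >= 20 dB in the 20-24 band (mid-window)."""
        trial = sine_trial([10.0, 10.0])
        banded = filter_bank(trial)
        mid = slice(250, 750)
        amp_in = np.abs(banded[0][0, mid]).max()
        amp_out = np.abs(banded[3][0, mid]).max()
        assert amp_in > 0.9
        assert 20 * np.log10(amp_in / amp_out) > 20

    def test_zero_signal_zero_output(self):
        trial = EpochedTrial(np.zeros((2, 1000)), label=0, fs=FS)
        assert np.all(filter_bank(trial) == 0.0)

    def test_band_above_nyquist_rejected(self):
        trial = sine_trial([10.0, 10.0])
        spec = FilterBankSpec(bands=((100.0, 130.0),))
        with pytest.raises(ValueError, match="Nyquist"):
            filter_bank(trial, spec)


class TestWelchBandPower:
    def test_parseval_oracle_sinusoid(self):
        """Unit 10 Hz sinusoid carries A^2/2 = 0.5 within its band."""
        t = np.arange(1000) / FS
        power = welch_band_power(np.cos(2 * np.pi * 10 * t), (8.0, 12.0), FS)
        assert abs(power - 0.5) / 0.5 < 0.05

    def test_zero_signal(self):
        assert welch_band_power(np.zeros(1000), (8.0, 12.0), FS) == 0.0

    def test_white_noise_flat_spectrum_oracle(self, rng):
        """White noise of variance v carries ~ v * bandwidth / nyquist per band."""
        v = 4.0
        x = np.sqrt(v) * rng.standard_normal(250 * 40)
        power = welch_band_power(x, (20.0, 30.0), FS)
        expected = v * 10.0 / 125.0
        assert abs(power - expected) / expected < 0.15

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError, match="Welch segment"):
            welch_band_power(np.zeros(100), (8.0, 12.0), FS)


class TestBuildGraph:
    def test_feature_shape_22_by_8(self, rng):
        trial = EpochedTrial(rng.normal(size=(22, 1000)), label=2, fs=FS)
        sample = build_graph(trial)
        assert sample.features.shape == (22, 8)
        assert sample.adjacency.shape == (22, 22)
        assert sample.label == 2

    def test_features_nonnegative(self, rng):
        trial = EpochedTrial(rng.normal(size=(6, 1000)), label=0, fs=FS)
        assert build_graph(trial).features.min() >= 0.0

    def test_adjacency_contract(self, rng):
        trial = EpochedTrial(rng.normal(size=(6, 1000)), label=0, fs=FS)
        adj = build_graph(trial).adjacency
        np.testing.assert_array_equal(np.diag(adj), 0.0)
        np.testing.assert_allclose(adj, adj.T)

    def test_deterministic(self, rng):
        trial = EpochedTrial(rng.normal(size=(5, 1000)), label=0, fs=FS)
        g1 = build_graph(trial)
        g2 = build_graph(trial)
        np.testing.assert_array_equal(g1.adjacency, g2.adjacency)
        np.testing.assert_array_equal(g1.features, g2.features)

    def test_dataset_stacking(self, rng):
        trials = [
            EpochedTrial(rng.normal(size=(5, 1000)), label=k % 2, fs=FS)
            for k in range(4)
        ]
        ds = build_graph_dataset(trials, channel_labels=[f"c{i}" for i in range(5)])
        assert len(ds) == 4
        assert ds.adjacency.shape == (4, 5, 5)
        assert ds.features.shape == (4, 5, 8)
        np.testing.assert_array_equal(ds.labels, [0, 1, 0, 1])

    def test_per_band_plv_averages_band_matrices(self, rng):
        trial = EpochedTrial(rng.normal(size=(4, 1000)), label=0, fs=FS)
        spec = FilterBankSpec()
        expected = np.mean(
            [compute_plv_matrix(trial, band=b) for b in spec.bands], axis=0
        )
        sample = build_graph(trial, plv_band="per-band")
        from sfegat.graph_construction import standardize_plv, threshold_adjacency

        np.testing.assert_allclose(
            sample.adjacency, threshold_adjacency(standardize_plv(expected))
        )

    def test_log10_feature_scale(self, rng):
        trial = EpochedTrial(rng.normal(size=(4, 1000)), label=0, fs=FS)
        raw = build_graph(trial).features
        logged = build_graph(trial, feature_scale="log10").features
        np.testing.assert_allclose(logged, np.log10(raw + 1e-12))

    def test_unknown_options_rejected(self, rng):
        trial = EpochedTrial(rng.normal(size=(4, 1000)), label=0, fs=FS)
        with pytest.raises(ValueError, match="plv_band"):
            build_graph(trial, plv_band="wavelet")
        with pytest.raises(ValueError, match="feature_scale"):
            build_graph(trial, feature_scale="zscore")

    def test_dataset_round_trip(self, rng, tmp_path, small_graph_dataset):
        path = tmp_path / "graphs.npz"
        small_graph_dataset.save(path)
        loaded = type(small_graph_dataset).load(path)
        np.testing.assert_array_equal(loaded.adjacency, small_graph_dataset.adjacency)
        np.testing.assert_array_equal(loaded.features, small_graph_dataset.features)
        np.testing.assert_array_equal(loaded.labels, small_graph_dataset.labels)
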