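"""Signal generators, SNR mixing, ground truth, and epoch generation."""
import numpy as np
import pytest
from scipy import signal as sps

from eegxai import simulate as sim


class TestGaussianPeak:
    def test_p1_like_component_peaks_at_latency(self):
        w = sim.gaussian_peak(60.0, 50.0, 10.0, +1)
        assert w.max() == pytest.approx(10.0)
        assert abs(np.argmax(w) - 15) <= 1  # 60 ms at 250 Hz

    def test_zero_amplitude_is_silent(self):
        assert np.all(sim.gaussian_peak(500.0, 100.0, 0.0, +1) == 0)

    def test_polarity_negates_exactly(self):
        up = sim.gaussian_peak(500.0, 100.0, 7.0, +1)
        down = sim.gaussian_peak(500.0, 100.0, 7.0, -1)
        np.testing.assert_array_equal(down, -up)

    def test_rejects_nonpositive_width(self):
        with pytest.raises(ValueError):
            sim.gaussian_peak(500.0, 0.0, 1.0)


class TestBandBurst:
    @pytest.mark.parametrize("band", [(3.0, 8.0), (8.0, 13.0), (14.0, 30.0), (30.0, 58.0)])
    def test_power_concentrated_in_band(self, band):
        rng = np.random.default_rng(42)
        psd = 0.0
        for _ in range(200):
            w = sim.band_burst(band, 2.0, 350.0, 500.0, rng=rng)
            f, p = sps.periodogram(w, fs=sim.FS)
            psd = psd + p
        lo, hi = band[0] - 2.0, band[1] + 2.0
        frac = psd[(f >= lo) & (f <= hi)].sum() / psd.sum()
        assert frac >= 0.80

    @pytest.mark.parametrize("band", [(3.0, 8.0), (8.0, 13.0), (14.0, 30.0), (30.0, 58.0)])
    def test_mean_psd_peak_inside_band(self, band):
        rng = np.random.default_rng(7)
        psd = 0.0
        for _ in range(200):
            w = sim.band_burst(band, 2.0, 350.0, 500.0, rng=rng)
            f, p = sps.periodogram(w, fs=sim.FS)
            psd = psd + p
        fpeak = f[np.argmax(psd)]
        assert band[0] <= fpeak <= band[1]

    def test_energy_outside_envelope_small(self):
        rng = np.random.default_rng(3)
        center, width = 350.0, 400.0
        t_ms = np.arange(sim.N_SAMPLES) / sim.FS * 1000
        inside = np.abs(t_ms - center) <= width / 2
        frac = []
        for _ in range(100):
            w = sim.band_burst((8.0, 13.0), 2.0, center, width, rng=rng)
            e = w**2
            frac.append(e[~inside].sum() / e.sum())
        assert np.mean(frac) < 0.05

    def test_zero_amplitude(self):
        w = sim.band_burst((8.0, 13.0), 0.0, 350.0, 500.0, rng=np.random.default_rng(0))
        assert np.all(w == 0)

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            sim.band_burst((100.0, 130.0), 1.0, 350.0, 500.0, rng=np.random.default_rng(0))


class TestPinkNoise:
    def test_psd_slope_near_minus_one(self):
        rng = np.random.default_rng(1)
        pn = sim.pink_noise(200, sim.N_SAMPLES, 5.0, rng)
        f, p = sps.periodogram(pn, fs=sim.FS, axis=1)
        pm = p.mean(axis=0)
        sel = (f >= 1) & (f <= 100)
        slope = np.polyfit(np.log10(f[sel]), np.log10(pm[sel]), 1)[0]
        assert -1.3 <= slope <= -0.7

    def test_rms_exact(self):
        pn = sim.pink_noise(8, 250, 5.0, np.random.default_rng(2))
        np.testing.assert_allclose(np.sqrt((pn**2).mean(axis=1)), 5.0, atol=1e-9)

    def test_independent_seeds_uncorrelated(self):
        a = sim.pink_noise(200, 250, 1.0, np.random.default_rng(10)).ravel()
        b = sim.pink_noise(200, 250, 1.0, np.random.default_rng(11)).ravel()
        assert abs(np.corrcoef(a, b)[0, 1]) < 0.1


class TestMixToSnr:
    def test_zero_db_equalizes_power(self):
        rng = np.random.default_rng(0)
        s = rng.standard_normal((250, 62))
        n = 3 * rng.standard_normal((250, 62))
        m = sim.mix_to_snr(s, n, 0.0)
        assert np.mean((m - s) ** 2) == pytest.approx(np.mean(s**2), rel=1e-12)

    @pytest.mark.parametrize("snr", list(sim.SNR_LEVELS_DB))
    def test_measured_snr_within_microdecibel(self, snr):
        rng = np.random.default_rng(int(abs(snr) * 10))
        s = rng.standard_normal((250, 62))
        n = rng.standard_normal((250, 62)) * 0.3
        m = sim.mix_to_snr(s, n, snr)
        measured = 10 * np.log10(np.mean(s**2) / np.mean((m - s) ** 2))
        assert abs(measured - snr) < 1e-6

    def test_minus_23_db_noise_power_ratio(self):
        rng = np.random.default_rng(9)
        s = rng.standard_normal((250, 62))
        n = rng.standard_normal((250, 62))
        m = sim.mix_to_snr(s, n, -23.0)
        assert np.mean((m - s) ** 2) / np.mean(s**2) == pytest.approx(10**2.3, rel=1e-9)

    def test_snr_invariant_to_signal_scale(self):
        rng = np.random.default_rng(4)
        s = rng.standard_normal((250, 62))
        n = rng.standard_normal((250, 62))
        for sig in (s, 2 * s):
            m = sim.mix_to_snr(sig, n, -12.0)
            measured = 10 * np.log10(np.mean(sig**2) / np.mean((m - sig) ** 2))
            assert measured == pytest.approx(-12.0, abs=1e-9)

    def test_zero_power_rejected(self):
        with pytest.raises(ValueError):
            sim.mix_to_snr(np.zeros((250, 62)), np.ones((250, 62)), 0.0)


class TestGroundTruth:
    def test_normalized_and_masked(self, temporal_leadfield):
        w = sim.gaussian_peak(60.0, 50.0, 8.0)
        rel, mask, topo = sim.ground_truth_map(temporal_leadfield, 0, w)
        assert rel.max() == pytest.approx(1.0)
        np.testing.assert_array_equal(mask, (rel > 0).astype(np.uint8))
        # outside the tapered window the mask is zero
        t_ms = np.arange(250) * 4.0
        outside = np.abs(t_ms - 60.0) > 50.0
        assert mask[outside].sum() == 0
        summed = rel.sum(axis=0)
        np.testing.assert_allclose(topo, summed / summed.max())

    def test_left_source_topography_left_lateralized(self, sensorimotor_leadfield, montage):
        w = sim.gaussian_peak(500.0, 100.0, 5.0)
        _, _, topo = sim.ground_truth_map(sensorimotor_leadfield, 0, w)  # L superioparietal
        ex = montage.positions[:, 0]
        assert topo[ex < 0].sum() > topo[ex > 0].sum()

    def test_all_zero_waveform_rejected(self, temporal_leadfield):
        with pytest.raises(ValueError):
            sim.ground_truth_map(temporal_leadfield, 0, np.zeros(250))


class TestGenerateCondition:
    def test_temporal_shape_balance_and_determinism(self, small_temporal):
        epochs, gt = small_temporal
        assert epochs.data.shape == (40, 250, 62)
        assert np.bincount(epochs.labels).tolist() == [10, 10, 10, 10]
        assert gt.relevance.shape == epochs.data.shape
        again, _ = sim.generate_condition("temporal", -3.5, 10, seed=11)
        np.testing.assert_array_equal(epochs.data, again.data)

    def test_spatial_has_two_hemisphere_classes(self):
        epochs, gt = sim.generate_condition("spatial", -3.5, 4, seed=5)
        assert sorted(np.unique(epochs.labels)) == [0, 1]
        mont = sim.build_default_montage()
        ex = mont.positions[:, 0]
        # class-mean ground-truth topographies lateralize to opposite sides
        topo0 = gt.topo[epochs.labels == 0].mean(axis=0)
        topo1 = gt.topo[epochs.labels == 1].mean(axis=0)
        assert topo0[ex < 0].sum() > topo0[ex > 0].sum()
        assert topo1[ex > 0].sum() > topo1[ex < 0].sum()

    def test_unknown_condition_rejected(self):
        with pytest.raises(ValueError):
            sim.generate_condition("fractal", -3.5, 1, seed=0)

    def test_amplitude_law_shared_between_latency_classes(self):
        """Classes 1 and 2 differ in latency only: same amplitude distribution."""
        from scipy.stats import ks_2samp

        epochs, _ = sim.generate_condition("temporal", -3.5, 500, seed=21)
        md = epochs.metadata
        a1 = md[md.class_id == 0].amplitude_uV
        a2 = md[md.class_id == 1].amplitude_uV
        assert ks_2samp(a1, a2).pvalue > 0.01
        # and their latency distributions are far apart
        assert md[md.class_id == 0].latency_ms.max() < md[md.class_id == 1].latency_ms.min()

    def test_epoch_hdf5_roundtrip(self, small_temporal, tmp_path):
        epochs, gt = small_temporal
        path = tmp_path / "epochs.h5"
        sim.save_epochs(path, epochs, gt)
        loaded, gt2 = sim.load_epochs(path)
        np.testing.assert_allclose(loaded.data, epochs.data, atol=1e-4)
        np.testing.assert_array_equal(loaded.labels, epochs.labels)
        np.testing.assert_array_equal(gt2.mask, gt.mask)
        assert loaded.condition == "temporal" and loaded.snr_db == -3.5
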