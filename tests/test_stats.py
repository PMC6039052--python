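"""Spindle statistics: densities, distribution fits, co-occurrence, phases."""

import numpy as np
import pytest
from scipy import stats as sps

from spindlenet import stats as st
from spindlenet.detect import SpindleEvent


def ev(onset, offset, channel=0):
    return SpindleEvent(channel, onset, offset)


class TestDensity:
    def test_arithmetic(self):
        events = [ev(i * 10.0, i * 10.0 + 1.0) for i in range(12)]
        assert st.spindle_density(events, 120.0)[0] == pytest.approx(6.0)

    def test_empty(self):
        assert len(st.spindle_density([], 60.0)) == 0
        assert st.spindle_density([], 60.0, n_channels=3).tolist() == [0, 0, 0]

    def test_concatenation_averages(self):
        a = [ev(i * 10.0, i * 10.0 + 1.0) for i in range(6)]
        b = [ev(60 + i * 5.0, 60 + i * 5.0 + 1.0) for i in range(11)]
        da = st.spindle_density(a, 60.0)[0]
        db = st.spindle_density(b, 60.0)[0]
        dab = st.spindle_density(a + b, 120.0)[0]
        assert dab == pytest.approx((da + db) / 2)

    def test_bad_duration(self):
        with pytest.raises(ValueError):
            st.spindle_density([], 0.0)


class TestIsiFits:
    def test_lognormal_parameter_recovery(self):
        rng = np.random.default_rng(10)
        mu, sigma, n = 1.0, 0.5, 1000
        x = rng.lognormal(mu, sigma, n)
        fit = st.fit_isi_distributions(x)
        assert fit["ok"]
        se_mu = sigma / np.sqrt(n)
        se_sigma = sigma / np.sqrt(2 * n)
        assert abs(fit["lognormal"]["mu"] - mu) < 3 * se_mu
        assert abs(fit["lognormal"]["sigma"] - sigma) < 3 * se_sigma

    def test_exponential_mean_recovery(self):
        rng = np.random.default_rng(11)
        x = rng.exponential(8.0, 2000)
        fit = st.fit_isi_distributions(x)
        assert fit["exponential"]["mean"] == pytest.approx(x.mean())

    def test_insufficient_data_flagged(self):
        fit = st.fit_isi_distributions([1.0, 2.0, 3.0])
        assert not fit["ok"]
        assert fit["n"] == 3

    def test_lilliefors_type_one_error_calibrated(self):
        # Gaussian data should be rejected at roughly the nominal 5% rate
        rng = np.random.default_rng(12)
        rejections = 0
        for _ in range(200):
            x = 10.0 + rng.standard_normal(1000)
            fit = st.fit_isi_distributions(x)
            rejections += fit["lilliefors"]["pvalue"] < 0.05
        assert rejections / 200 <= 0.10

    def test_lilliefors_rejects_lognormal(self):
        rng = np.random.default_rng(13)
        x = rng.lognormal(1.0, 0.8, 1000)
        fit = st.fit_isi_distributions(x)
        assert fit["lilliefors"]["pvalue"] < 0.01

    def test_ks_identical_sample_zero(self):
        x = np.linspace(1, 10, 100)
        assert st.ks_compare(x, x)["statistic"] == 0.0


class TestCooccurrence:
    def test_identical_lists(self):
        a = [ev(i * 10.0, i * 10.0 + 1.0) for i in range(10)]
        assert st.cooccurrence_probability(a, list(a)) == 1.0

    def test_disjoint(self):
        a = [ev(0.0, 1.0)]
        b = [ev(100.0, 101.0)]
        assert st.cooccurrence_probability(a, b) == 0.0

    def test_sublist_asymmetry(self):
        a = [ev(i * 10.0, i * 10.0 + 1.0) for i in range(10)]
        b = a[:5]
        assert st.cooccurrence_probability(a, b) == pytest.approx(0.5)
        assert st.cooccurrence_probability(b, a) == pytest.approx(1.0)

    def test_no_events_nan(self):
        assert np.isnan(st.cooccurrence_probability([], [ev(0, 1)]))

    def test_probability_bounds(self):
        rng = np.random.default_rng(3)
        a = [ev(t, t + 0.8) for t in np.sort(rng.uniform(0, 300, 40))]
        b = [ev(t, t + 0.8) for t in np.sort(rng.uniform(0, 300, 25))]
        for x, y in ((a, b), (b, a)):
            p = st.cooccurrence_probability(x, y)
            assert 0.0 <= p <= 1.0

    def test_active_channel_counts(self):
        # one co-occurring event on 3 channels, one isolated on 1 channel
        a = [ev(0.0, 1.0, c) for c in range(3)] + [ev(50.0, 51.0, 0)]
        b = [ev(0.2, 1.2, 0)]
        counts = st.active_channel_counts(a, b)
        assert counts["with_cooccurrence"] == pytest.approx(3.0)
        assert counts["without_cooccurrence"] == pytest.approx(1.0)


class TestDelays:
    def test_sign_convention(self):
        # core onset 1.0 s, matrix onset 1.3 s: core precedes, delay -0.3
        d = st.onset_delays([ev(1.0, 2.0)], [ev(1.3, 2.3)])
        assert d.tolist() == pytest.approx([-0.3])

    def test_window_exclusion(self):
        d = st.onset_delays([ev(1.0, 2.0)], [ev(5.0, 6.0)])
        assert len(d) == 0

    def test_matches_enumeration(self):
        core_on = [1.0, 10.0, 20.0]
        mat_on = [1.5, 9.8, 40.0]
        core = [ev(t, t + 1) for t in core_on]
        mat = [ev(t, t + 1) for t in mat_on]
        d = sorted(st.onset_delays(core, mat).tolist())
        assert d == pytest.approx([-0.5, 0.2])

    def test_each_matrix_event_used_once(self):
        core = [ev(1.0, 2.0), ev(1.2, 2.2)]
        # merged into one layer event -> single pairing
        d = st.onset_delays(core, [ev(1.1, 2.1)])
        assert len(d) == 1


class TestSpatialCorrelation:
    def _lfp(self, n=20000, n_ch=4, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        t = np.arange(n) / 1000.0
        common = np.sin(2 * np.pi * 13.0 * t)
        return np.stack(
            [common + noise * rng.standard_normal(n) for _ in range(n_ch)],
            axis=1)

    def test_identical_channels_perfectly_correlated(self):
        lfp = self._lfp(noise=0.0)
        df = st.spatial_correlation(lfp, 1000.0, [ev(2.0, 18.0)])
        assert np.allclose(df["corr"], 1.0, atol=1e-6)

    def test_independent_noise_uncorrelated(self):
        rng = np.random.default_rng(5)
        lfp = rng.standard_normal((60000, 4))
        df = st.spatial_correlation(lfp, 1000.0, [ev(5.0, 55.0)])
        # ~7200 effective band-limited samples; 3 SE margin
        assert np.abs(df["corr"]).max() < 0.1

    def test_correlation_decreases_with_noise(self):
        vals = []
        for noise in (0.1, 1.0, 4.0):
            lfp = self._lfp(noise=noise, seed=6)
            df = st.spatial_correlation(lfp, 1000.0, [ev(2.0, 18.0)])
            vals.append(df["corr"].mean())
        assert vals[0] > vals[1] > vals[2]

    def test_no_epochs_rejected(self):
        with pytest.raises(ValueError, match="no spindle epochs"):
            st.spatial_correlation(np.zeros((20000, 3)), 1000.0, [])


class TestSpikePhase:
    RATE = 1000.0

    def _lfp_cos(self, duration=60.0, freq=10.0):
        t = np.arange(int(duration * self.RATE)) / self.RATE
        return np.cos(2 * np.pi * freq * t), t

    def test_peak_locked_spikes_near_phase_zero(self):
        lfp, t = self._lfp_cos()
        peaks = np.arange(5.0, 55.0, 0.1)  # every cosine peak
        events = [ev(4.0, 56.0)]
        out = st.spike_phase_distribution(peaks, lfp, self.RATE, events)
        assert out["ok"]
        # circular mean at the peak -> phase 0 in this convention
        assert abs(np.angle(out["mean_vector"])) < 0.2
        assert abs(out["mean_vector"]) > 0.9

    def test_uniform_spikes_flat_histogram(self):
        lfp, t = self._lfp_cos()
        rejections = 0
        rng = np.random.default_rng(9)
        for _ in range(200):
            spikes = rng.uniform(5.0, 55.0, 300)
            out = st.spike_phase_distribution(spikes, lfp, self.RATE,
                                              [ev(4.0, 56.0)], n_bins=20)
            counts, _ = np.histogram(out["phases"],
                                     bins=np.linspace(-np.pi, np.pi, 21))
            chi2 = ((counts - counts.mean()) ** 2 / counts.mean()).sum()
            rejections += chi2 > sps.chi2.ppf(0.95, 19)
        assert rejections / 200 <= 0.10

    def test_histogram_normalized(self):
        lfp, t = self._lfp_cos()
        rng = np.random.default_rng(4)
        out = st.spike_phase_distribution(rng.uniform(5, 55, 500), lfp,
                                          self.RATE, [ev(4.0, 56.0)])
        width = np.diff(out["edges"])
        assert (out["density"] * width).sum() == pytest.approx(1.0)

    def test_too_few_spikes_excluded(self):
        lfp, t = self._lfp_cos(duration=20.0)
        out = st.spike_phase_distribution([6.0, 7.0], lfp, self.RATE,
                                          [ev(5.0, 15.0)])
        assert not out["ok"]


class TestMergeEvents:
    def test_cross_channel_merge(self):
        events = [ev(1.0, 2.0, 0), ev(2.1, 3.0, 1), ev(10.0, 11.0, 0)]
        spans = st.merge_events(events, gap=0.3)
        assert spans == [(1.0, 3.0), (10.0, 11.0)]
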