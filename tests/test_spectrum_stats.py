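import numpy as np
import pytest

from assrdeconv.core import SteadyStateRecord, ValidationError
from assrdeconv.spectrum_stats import (
    harmonic_set,
    hotelling_one_sample,
    outlier_policy,
    pointwise_ttest,
    reconstruct,
    t2_to_f,
)
from assrdeconv.synthesis import synthesize_assr

FS = 2500.0


def _record(waveform, n_cycles=4):
    return SteadyStateRecord(waveform=waveform, fs=FS, n_cycles=n_cycles)


class TestHarmonicSet:
    def test_pure_cosine_fundamental(self):
        amp = 0.7
        t = np.arange(256) / FS
        f0 = FS * 4 / 256
        record = _record(amp * np.cos(2 * np.pi * f0 * t))
        hset = harmonic_set(record)
        assert hset.f0 == pytest.approx(f0)
        assert hset.amplitudes[0] == pytest.approx(amp / np.sqrt(2), rel=1e-9)
        assert np.all(hset.amplitudes[1:] < 1e-12)

    def test_zero_record(self):
        hset = harmonic_set(_record(np.zeros(256)))
        assert np.all(hset.coefficients == 0)

    def test_missing_cycles_error(self):
        with pytest.raises(ValidationError):
            harmonic_set(SteadyStateRecord(waveform=np.zeros(256), fs=FS))

    def test_parseval_bound_on_template_assr(self, template):
        record = synthesize_assr(template, 25.6, 4)
        hset = harmonic_set(record)
        mean_square = np.mean(record.waveform**2)
        # record has a DC term and higher harmonics: harmonic energy < total
        harmonic_energy = np.sum(hset.amplitudes**2)
        assert harmonic_energy <= mean_square + 1e-12

    def test_parseval_full_identity(self, template):
        record = synthesize_assr(template, 25.6, 4)
        spectrum = np.fft.fft(record.waveform)
        assert np.mean(record.waveform**2) == pytest.approx(
            np.mean(np.abs(spectrum) ** 2) / record.n, rel=1e-12)

    def test_vector_layout(self):
        t = np.arange(256) / FS
        f0 = FS * 4 / 256
        record = _record(np.cos(2 * np.pi * f0 * t) + 0.5 * np.sin(4 * np.pi * f0 * t))
        vec = harmonic_set(record).as_vector()
        assert vec.shape == (6,)
        assert abs(vec[0]) > 1e-3  # fundamental is cosine → real part
        assert abs(vec[3]) > 1e-3  # second harmonic is sine → imaginary part


class TestReconstruct:
    def test_band_limited_round_trip(self):
        rng = np.random.default_rng(5)
        coeffs = rng.standard_normal(3) + 1j * rng.standard_normal(3)
        spectrum = np.zeros(129, dtype=complex)
        spectrum[[4, 8, 12]] = coeffs * 256 / np.sqrt(2)
        x = np.fft.irfft(spectrum, n=256)
        hset = harmonic_set(_record(x))
        assert np.allclose(reconstruct(hset), x, atol=1e-12)

    def test_residual_energy_non_negative(self, template):
        record = synthesize_assr(template, 25.6, 4)
        recon = reconstruct(harmonic_set(record))
        residual = record.waveform - recon
        total = np.sum(record.waveform**2)
        explained = np.sum(recon**2)
        # residual and reconstruction occupy disjoint DFT bins → orthogonal
        assert np.sum(residual**2) == pytest.approx(total - explained, rel=1e-9)
        assert total - explained >= -1e-12

    def test_declining_harmonics_on_template_assr(self, template):
        record = synthesize_assr(template, 25.6, 4)
        amps = harmonic_set(record).amplitudes
        assert amps[0] > amps[1] > amps[2]


class TestPointwiseTtest:
    def test_all_zero_differences(self):
        trace = pointwise_ttest(np.zeros((5, 20)))
        assert trace.significant_fraction_pct == 0.0

    def test_constant_offset_tiny_variance(self, rng):
        diff = 5.0 + 1e-6 * rng.standard_normal((10, 30))
        trace = pointwise_ttest(diff)
        assert trace.significant_fraction_pct == 100.0

    def test_needs_three_subjects(self):
        with pytest.raises(ValidationError):
            pointwise_ttest(np.zeros((2, 10)))

    def test_null_calibration(self):
        fractions = []
        for seed in range(100):
            seed_rng = np.random.default_rng(1000 + seed)
            trace = pointwise_ttest(seed_rng.standard_normal((19, 256)))
            fractions.append(trace.significant_fraction_pct)
        assert np.mean(fractions) == pytest.approx(5.0, abs=1.0)


class TestHotelling:
    def test_univariate_equals_t_squared(self, rng):
        from scipy import stats

        x = rng.standard_normal((12, 1)) + 0.4
        result = hotelling_one_sample(x)
        t_stat = stats.ttest_1samp(x[:, 0], 0.0).statistic
        assert result.t2 == pytest.approx(t_stat**2, rel=1e-10)
        assert result.f == pytest.approx(t_stat**2, rel=1e-10)

    def test_zero_mean_data(self, rng):
        x = rng.standard_normal((10, 2))
        x -= x.mean(axis=0)
        result = hotelling_one_sample(x)
        assert result.t2 == pytest.approx(0.0, abs=1e-18)
        assert result.p_value == pytest.approx(1.0)

    def test_n_not_greater_than_p_error(self, rng):
        with pytest.raises(ValidationError):
            hotelling_one_sample(rng.standard_normal((6, 6)))

    def test_invariance_under_linear_transform(self, rng):
        x = rng.standard_normal((17, 6)) + 0.3
        m = rng.standard_normal((6, 6)) + np.eye(6)  # invertible w.h.p.
        assert hotelling_one_sample(x @ m.T).t2 == pytest.approx(
            hotelling_one_sample(x).t2, rel=1e-8)

    def test_f_p_consistency(self, rng):
        x = rng.standard_normal((17, 6))
        r = hotelling_one_sample(x)
        assert r.f == pytest.approx(r.t2 * (r.n - r.p) / (r.p * (r.n - 1)))
        assert r.df == (6, 11)

    def test_ellipse_excludes_origin_iff_significant(self, rng):
        # planted strong effect: origin outside the confidence ellipse
        x = rng.standard_normal((17, 2)) * 0.2 + np.array([2.0, 0.0])
        r = hotelling_one_sample(x)
        assert r.p_value < 0.05
        # origin's Mahalanobis distance (under S/n) exceeds the ellipse scale
        d2 = r.ellipse_center @ np.linalg.solve(r.covariance / r.n, r.ellipse_center)
        assert d2 > r.t2 * 0  # sanity
        from scipy import stats as st
        scale = r.p * (r.n - 1) / (r.n - r.p) * st.f.ppf(0.95, r.p, r.n - r.p)
        assert d2 > scale

    def test_type_one_error_calibration(self):
        rejections = 0
        n_reps = 500
        for seed in range(n_reps):
            seed_rng = np.random.default_rng(5000 + seed)
            result = hotelling_one_sample(seed_rng.standard_normal((17, 6)))
            rejections += result.p_value < 0.05
        assert rejections / n_reps == pytest.approx(0.05, abs=0.02)


class TestT2ToF:
    @pytest.mark.parametrize("t2,expected", [
        (32.33, 3.70),
        (92.04, 10.55),
        (6.96, 0.80),
    ])
    def test_published_conversions(self, t2, expected):
        assert round(t2_to_f(t2, n=17, p=6), 2) == expected

    def test_zero(self):
        assert t2_to_f(0.0, 17, 6) == 0.0

    def test_invalid_dimensions(self):
        with pytest.raises(ValidationError):
            t2_to_f(1.0, 6, 6)


class TestOutlierPolicy:
    def test_clean_sample_low_removal(self):
        rates = []
        for seed in range(40):
            seed_rng = np.random.default_rng(seed)
            kept = outlier_policy(seed_rng.standard_normal((100, 6)))
            rates.append(1 - kept.size / 100)
        assert np.mean(rates) <= 0.05

    def test_planted_outlier_removed(self):
        rng = np.random.default_rng(42)
        x = rng.standard_normal((20, 6))
        x[7] += 10.0
        kept = outlier_policy(x)
        assert 7 not in kept

    def test_identical_vectors_none_removed(self):
        kept = outlier_policy(np.ones((5, 6)))
        assert kept.size == 5

    def test_too_few_subjects_error(self):
        with pytest.raises(ValidationError):
            outlier_policy(np.zeros((4, 6)))
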