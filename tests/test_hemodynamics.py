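"""Canonical HRF, convolution, drift basis, deconvolution, spectra."""

import numpy as np
import pytest

from ppikit import (
    BoldSeries,
    HRFSpec,
    canonical_hrf,
    convolve_causal,
    dct_highpass,
    deconvolve,
)
from ppikit.hemodynamics import _cosine_columns, band_power, power_spectrum


class TestCanonicalHRF:
    def test_zero_at_origin_and_peak_near_five_seconds(self):
        kernel = canonical_hrf(HRFSpec(dt=0.1))
        assert kernel[0] == 0.0
        assert len(kernel) == 320
        peak_time = np.argmax(kernel) * 0.1
        assert 4.5 <= peak_time <= 5.5
        assert kernel.sum() * 0.1 > 0  # integrates to a positive response

    def test_same_closed_form_at_different_sampling_steps(self):
        fine = canonical_hrf(HRFSpec(dt=0.1))
        coarse = canonical_hrf(HRFSpec(dt=0.5))
        # every coarse sample falls on a fine-grid point
        assert np.allclose(coarse, fine[::5], atol=1e-9)

    @pytest.mark.parametrize(
        "kwargs",
        [{"dt": -0.5}, {"response_dispersion": 0.0}, {"kernel_length": 2.0}],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            HRFSpec(**kwargs)


class TestConvolveCausal:
    def test_identity_kernel_returns_input(self, rng):
        x = rng.standard_normal(50)
        dt = 0.645
        assert np.allclose(convolve_causal(x, np.array([1.0 / dt]), dt), x)

    def test_zeros_stay_zeros(self):
        kernel = canonical_hrf(HRFSpec(dt=0.5))
        assert np.all(convolve_causal(np.zeros(80), kernel, 0.5) == 0)

    def test_constant_input_plateaus_at_kernel_integral(self):
        dt = 0.5
        kernel = canonical_hrf(HRFSpec(dt=dt))
        out = convolve_causal(np.ones(200), kernel, dt)
        assert out[-1] == pytest.approx(dt * kernel.sum(), rel=1e-12)


class TestDCTHighpass:
    @pytest.mark.parametrize(
        "n_scans,tr,expected",
        [(225, 0.645, 2 / 290.25), (93, 1.4, 2 / 260.4)],
    )
    def test_effective_cutoffs_for_both_run_layouts(self, n_scans, tr, expected):
        basis = dct_highpass(n_scans, tr, 128.0)
        assert basis.effective_cutoff == pytest.approx(expected, rel=1e-12)
        assert basis.n_drift == 2
        # printed precision: 0.0069 Hz and 0.0077 Hz
        assert round(basis.effective_cutoff, 4) in (0.0069, 0.0077)

    def test_columns_orthonormal(self):
        basis = dct_highpass(120, 2.0, 128.0)
        gram = basis.matrix.T @ basis.matrix
        assert np.allclose(gram, np.eye(basis.matrix.shape[1]), atol=1e-12)

    def test_long_cutoff_keeps_only_constant(self):
        basis = dct_highpass(50, 1.0, 2 * 50 * 1.0 + 10)
        assert basis.n_drift == 0
        assert basis.matrix.shape[1] == 1

    def test_cutoff_below_two_tr_is_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            dct_highpass(100, 2.0, 3.0)

    def test_projection_removes_retained_drift_frequency(self):
        n, tr = 225, 0.645
        basis = dct_highpass(n, tr, 128.0)
        # cosine at the first retained drift frequency
        drift = _cosine_columns(n, 2)[:, 1]
        proj = basis.matrix @ (basis.matrix.T @ drift)
        resid = drift - proj
        assert resid.var() <= 0.01 * drift.var()


class TestDeconvolve:
    def test_zero_series_gives_zero_estimate(self):
        est = deconvolve(BoldSeries(np.zeros(60), tr=1.0), HRFSpec())
        assert np.allclose(est.values, 0) and np.allclose(est.residual, 0)

    def test_noiseless_band_limited_round_trip(self, rng):
        n, tr = 225, 0.645
        spec = HRFSpec()
        basis = _cosine_columns(n, n)
        coefs = np.zeros(n)
        coefs[:5] = rng.standard_normal(5)
        z = basis @ coefs
        x = convolve_causal(z, canonical_hrf(spec.at_dt(tr)), tr)
        est = deconvolve(BoldSeries(x, tr=tr), spec)
        assert np.corrcoef(est.values, z)[0, 1] > 0.99
        assert np.corrcoef(est.reconvolved, x)[0, 1] > 0.999
        # residual identity: source = reconvolved + residual
        assert np.allclose(est.reconvolved + est.residual, x)

    def test_round_trip_relative_error_tiny_at_vanishing_regularization(self, rng):
        n, tr = 120, 1.0
        spec = HRFSpec()
        basis = _cosine_columns(n, 24)
        z = basis @ rng.standard_normal(24)
        x = convolve_causal(z, canonical_hrf(spec.at_dt(tr)), tr)
        est = deconvolve(BoldSeries(x, tr=tr), spec, basis_order=24, reg_weight=1e-12)
        rel = np.linalg.norm(x - est.reconvolved) / np.linalg.norm(x)
        assert rel < 1e-6

    def test_high_frequency_band_suppressed(self):
        tr, n = 0.645, 225
        t = np.arange(n) * tr
        x = np.sin(2 * np.pi * 0.01 * t) + 0.5 * np.sin(2 * np.pi * 0.3 * t)
        series = BoldSeries(x, tr=tr)
        est = deconvolve(series, HRFSpec(), reg_weight=1.0)
        f_raw, p_raw = power_spectrum(series)
        f_fit, p_fit = power_spectrum(BoldSeries(est.reconvolved, tr=tr))
        assert band_power(f_fit, p_fit, 0.2, 0.4) < 0.2 * band_power(f_raw, p_raw, 0.2, 0.4)

    def test_shrinkage_monotone_in_regularization_weight(self, rng):
        tr, n = 0.645, 225
        x = rng.standard_normal(n)
        series = BoldSeries(x, tr=tr)
        powers = []
        for w in [1e-3, 1e-1, 1e1, 1e3]:
            est = deconvolve(series, HRFSpec(), reg_weight=w)
            f, p = power_spectrum(BoldSeries(est.reconvolved, tr=tr))
            powers.append(band_power(f, p, 0.2, 0.4))
        assert all(b <= a * (1 + 1e-9) for a, b in zip(powers, powers[1:]))

    def test_basis_order_cannot_exceed_scan_count(self):
        with pytest.raises(ValueError):
            deconvolve(BoldSeries(np.zeros(10), tr=1.0), HRFSpec(), basis_order=11)


class TestPowerSpectrum:
    def test_constant_series_has_no_nonzero_frequency_power(self):
        freqs, power = power_spectrum(BoldSeries(np.full(64, 3.0), tr=1.0))
        assert np.allclose(power[freqs > 0], 0)

    def test_on_grid_sinusoid_peaks_at_its_frequency(self):
        n, tr = 128, 0.5
        f0 = 8 / (n * tr)  # exactly on the DFT grid
        x = np.sin(2 * np.pi * f0 * np.arange(n) * tr)
        freqs, power = power_spectrum(BoldSeries(x, tr=tr))
        assert freqs[np.argmax(power)] == pytest.approx(f0)
        assert freqs[-1] == pytest.approx(1 / (2 * tr))

    def test_total_power_matches_variance(self, rng):
        x = rng.standard_normal(100)
        _, power = power_spectrum(BoldSeries(x, tr=0.8))
        assert power.sum() == pytest.approx(x.var() * 100, rel=1e-10)
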