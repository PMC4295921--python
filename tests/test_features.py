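import numpy as np
import pytest

import specdcm as sd
from specdcm.features import (
    CrossSpectra,
    FrequencyGrid,
    MARModel,
    csd_to_ccf,
    default_grid,
    detrend,
    fit_mar,
    mar_from_csd,
    mar_to_csd,
)


def brute_force_mar_csd(mar, grid):
    """Direct per-frequency evaluation of the MAR transfer function."""
    n, p = mar.n_regions, mar.order
    out = np.empty((n, n, grid.n_bins), dtype=complex)
    for k, f in enumerate(grid.frequencies):
        M = np.eye(n, dtype=complex)
        for lag in range(1, p + 1):
            M -= mar.coefficients[lag - 1] * np.exp(-2j * np.pi * f * lag * mar.TR)
        H = np.linalg.inv(M)
        out[:, :, k] = mar.TR * H @ mar.innovation_covariance @ H.conj().T
    return out


def simulate_var(coeffs, sigma_chol, T, seed):
    p, n = coeffs.shape[0], coeffs.shape[1]
    rng = np.random.default_rng(seed)
    y = np.zeros((n, T + 100))
    for t in range(p, T + 100):
        acc = sigma_chol @ rng.standard_normal(n)
        for k in range(p):
            acc = acc + coeffs[k] @ y[:, t - 1 - k]
        y[:, t] = acc
    return y[:, 100:]


class TestDefaultGrid:
    def test_standard_band_for_tr2(self):
        g = default_grid(2.0)
        assert g.n_bins == 32
        assert g.frequencies[0] == pytest.approx(0.0078125)
        assert g.frequencies[-1] == pytest.approx(0.25)

    def test_two_bin_grid_is_the_band_endpoints(self):
        g = default_grid(2.0, n_bins=2)
        assert np.allclose(g.frequencies, [0.0078125, 0.25])

    def test_spacing_is_uniform(self):
        d = np.diff(default_grid(2.0).frequencies)
        assert np.ptp(d) < 1e-12

    def test_band_collapses_for_very_slow_sampling(self):
        with pytest.raises(ValueError, match="empty band"):
            default_grid(65.0)

    def test_grid_validation(self):
        with pytest.raises(ValueError):
            FrequencyGrid(np.array([0.25, 0.1]), 2.0)  # decreasing
        with pytest.raises(ValueError):
            FrequencyGrid(np.array([0.0, 0.1]), 2.0)  # zero frequency
        with pytest.raises(ValueError):
            FrequencyGrid(np.array([0.1, 0.3]), 2.0)  # beyond Nyquist


class TestFitMar:
    def test_white_noise_coefficients_vanish(self):
        rng = np.random.default_rng(0)
        Y = rng.standard_normal((2, 20000))
        mar = fit_mar(Y, p=4)
        assert np.max(np.abs(mar.coefficients)) < 5 / np.sqrt(20000) * 3

    def test_univariate_ar1_recovery(self):
        """Yule-Walker closed form: lag-1 coefficient = a, higher lags 0."""
        a = 0.5
        rng = np.random.default_rng(1)
        T = 10**5
        y = np.zeros(T)
        eps = rng.standard_normal(T)
        for t in range(1, T):
            y[t] = a * y[t - 1] + eps[t]
        mar = fit_mar(y[None, :], p=4)
        assert mar.coefficients[0, 0, 0] == pytest.approx(a, abs=0.01)
        assert np.max(np.abs(mar.coefficients[1:])) < 0.02

    def test_residual_variance_not_above_raw_variance(self):
        rng = np.random.default_rng(2)
        Y = rng.standard_normal((2, 500))
        mar = fit_mar(Y, p=4)
        assert np.all(np.diag(mar.innovation_covariance) <= Y.var(axis=1) * 1.05)

    def test_var_parameter_recovery_within_standard_errors(self):
        coeffs = np.array([[[0.4, 0.1], [0.0, 0.3]], [[0.1, 0.0], [0.0, -0.1]]])
        Y = simulate_var(coeffs, np.eye(2), 10**4, seed=3)
        mar = fit_mar(Y, p=2)
        se = 3.0 / np.sqrt(10**4)
        assert np.max(np.abs(mar.coefficients - coeffs)) < 3 * se * 3

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            fit_mar(np.zeros((4, 17)), p=4)


class TestMarToCsd:
    def test_white_mar_gives_flat_diagonal_spectrum(self, grid_tr2):
        mar = MARModel(np.zeros((4, 2, 2)), np.eye(2), TR=2.0)
        csd = mar_to_csd(mar, grid_tr2)
        d = np.einsum("iik->ik", csd.values).real
        assert np.allclose(d, 2.0)  # sigma^2 * TR
        off = csd.values[0, 1, :]
        assert np.allclose(off, 0.0)

    def test_univariate_ar1_closed_form(self, grid_tr2):
        a, s2, TR = 0.5, 1.3, 2.0
        mar = MARModel(np.full((1, 1, 1), a), np.array([[s2]]), TR=TR)
        csd = mar_to_csd(mar, grid_tr2)
        f = grid_tr2.frequencies
        expected = s2 * TR / np.abs(1 - a * np.exp(-2j * np.pi * f * TR)) ** 2
        assert np.allclose(csd.values[0, 0, :].real, expected, atol=1e-10)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_brute_force_transfer_evaluation(self, seed, grid_tr2):
        rng = np.random.default_rng(seed)
        coeffs = rng.normal(scale=0.15, size=(3, 2, 2))
        s = rng.normal(size=(2, 2))
        mar = MARModel(coeffs, s @ s.T + 0.5 * np.eye(2), TR=2.0)
        csd = mar_to_csd(mar, grid_tr2)
        oracle = brute_force_mar_csd(mar, grid_tr2)
        assert np.max(np.abs(csd.values - oracle)) < 1e-10

    def test_output_is_hermitian_everywhere(self, grid_tr2):
        rng = np.random.default_rng(9)
        coeffs = rng.normal(scale=0.1, size=(4, 3, 3))
        mar = MARModel(coeffs, np.eye(3), TR=2.0)
        mar_to_csd(mar, grid_tr2).validate()


class TestCsdToCcf:
    def test_flat_spectrum_concentrates_at_lag_zero(self, grid_tr2):
        v = np.zeros((1, 1, 32), dtype=complex)
        v[0, 0, :] = 1.0
        csd = CrossSpectra(v, grid_tr2)
        ccf = csd_to_ccf(csd, n_lags=8)
        assert ccf[0, 0, 8] == np.max(np.abs(ccf))

    def test_ar1_ccf_decays_geometrically(self):
        a, TR = 0.6, 1.0
        grid = FrequencyGrid(np.linspace(1e-4, 0.5, 4096), TR)
        mar = MARModel(np.full((1, 1, 1), a), np.eye(1), TR=TR)
        ccf = csd_to_ccf(mar_to_csd(mar, grid), n_lags=6)[0, 0]
        lags0 = ccf[6:]  # lags 0..6
        ratios = lags0[1:4] / lags0[:3]
        assert np.allclose(ratios, a, atol=0.02)

    def test_time_reversal_symmetry(self, grid_tr2):
        rng = np.random.default_rng(4)
        coeffs = rng.normal(scale=0.2, size=(2, 2, 2))
        mar = MARModel(coeffs, np.eye(2), TR=2.0)
        ccf = csd_to_ccf(mar_to_csd(mar, grid_tr2), n_lags=5)
        assert np.allclose(ccf[0, 1, :], ccf[1, 0, ::-1], atol=1e-10)

    def test_output_is_real_array(self, grid_tr2):
        mar = MARModel(np.zeros((1, 2, 2)), np.eye(2), TR=2.0)
        ccf = csd_to_ccf(mar_to_csd(mar, grid_tr2), n_lags=3)
        assert ccf.dtype.kind == "f"


class TestMarFromCsd:
    def test_round_trips_a_rational_spectrum(self):
        """Projecting a spectrum that is already MAR(p)-rational recovers the
        generating MAR (population Yule-Walker consistency)."""
        TR = 2.0
        coeffs = np.array([[[0.5, 0.1], [0.0, 0.35]], [[-0.1, 0.0], [0.05, 0.1]]])
        mar = MARModel(coeffs, np.array([[1.0, 0.2], [0.2, 0.8]]), TR=TR)
        fine = FrequencyGrid(np.linspace(1e-5, 0.25, 8192), TR)
        back = mar_from_csd(mar_to_csd(mar, fine), p=2)
        assert np.allclose(back.coefficients, coeffs, atol=5e-3)
        assert np.allclose(back.innovation_covariance, mar.innovation_covariance, atol=5e-3)

    def test_projection_is_idempotent_on_the_band(self, grid_tr2):
        rng = np.random.default_rng(7)
        coeffs = rng.normal(scale=0.15, size=(4, 2, 2))
        mar = MARModel(coeffs, np.eye(2), TR=2.0)
        fine = FrequencyGrid(np.linspace(1e-5, 0.25, 8192), 2.0)
        s1 = mar_to_csd(mar_from_csd(mar_to_csd(mar, fine), p=4), grid_tr2)
        s0 = mar_to_csd(mar, grid_tr2)
        rel = np.abs(s1.values - s0.values).max() / np.abs(s0.values).max()
        assert rel < 0.02


class TestValidator:
    def test_sample_csd_passes_validator(self, benchmark_run, grid_tr2):
        csd = sd.sample_csd(benchmark_run.bold, grid_tr2)
        csd.validate()

    def test_validator_rejects_non_hermitian(self, grid_tr2):
        v = np.zeros((2, 2, 32), dtype=complex)
        v[0, 1, :] = 1.0  # missing conjugate partner
        v[0, 0, :] = v[1, 1, :] = 1.0
        with pytest.raises(ValueError, match="Hermitian"):
            CrossSpectra(v, grid_tr2).validate()

    def test_hdf5_and_json_round_trips(self, tmp_path, grid_tr2):
        rng = np.random.default_rng(11)
        base = rng.normal(size=(2, 2, 32)) + 1j * rng.normal(size=(2, 2, 32))
        v = base + np.conj(np.transpose(base, (1, 0, 2)))
        idx = np.arange(2)
        v[idx, idx, :] = np.abs(v[idx, idx, :].real)
        csd = CrossSpectra(v, grid_tr2)
        csd.to_hdf5(tmp_path / "c.h5")
        back = CrossSpectra.from_hdf5(tmp_path / "c.h5")
        assert np.array_equal(back.values, v)
        assert back.grid.TR == 2.0
        csd.to_json(tmp_path / "c.json")
        back2 = CrossSpectra.from_json(tmp_path / "c.json")
        assert np.allclose(back2.values, v)

    def test_detrend_removes_mean_and_slope(self):
        t = np.arange(100, dtype=float)
        Y = np.stack([3 + 0.5 * t, -2 - 0.1 * t])
        Z = detrend(Y)
        assert np.allclose(Z, 0.0, atol=1e-9)
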