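import numpy as np
import pytest

import specdcm as sd
from specdcm.features import CrossSpectra
from specdcm.forward import NoiseSpectralParams, SpectralModel, predict_csd
from specdcm.inversion import (
    InversionConfig,
    ParameterMap,
    PriorSpec,
    data_vector,
    default_priors,
    free_energy,
    invert,
    variational_laplace,
)


class TestDefaultPriors:
    def test_parameter_count_and_zero_means(self):
        pmap = ParameterMap(4)
        priors = default_priors(4)
        # 12 extrinsic + 4 self + 8 hemo log-scales + 10 noise params
        assert pmap.size == 34
        assert priors.mean.size == 34
        assert np.array_equal(priors.mean, np.zeros(34))

    def test_hyperprior_values(self):
        priors = default_priors(4)
        assert priors.hyper_mean == 6.0
        assert priors.hyper_covariance == pytest.approx(1.0 / 128.0)

    def test_all_prior_variances_positive(self):
        priors = default_priors(3)
        assert np.all(np.diag(priors.covariance) > 0)

    def test_block_variances(self):
        pmap = ParameterMap(4)
        v = np.diag(default_priors(4).covariance)
        assert np.allclose(v[pmap.slices["extrinsic"]], 1 / 64)
        assert np.allclose(v[pmap.slices["self_logscale"]], 1 / 256)
        assert np.allclose(v[pmap.slices["transit"]], 1 / 256)
        assert np.allclose(v[pmap.slices["log_beta_neural"]], 1 / 64)


class TestParameterMap:
    def test_pack_unpack_round_trip(self, benchmark_conn, hemo4, grid_tr2):
        pmap = ParameterMap(4)
        rng = np.random.default_rng(0)
        theta = rng.normal(scale=0.1, size=pmap.size)
        model = pmap.unpack(theta, hemo4, grid_tr2)
        assert np.allclose(pmap.pack(model, hemo4), theta)

    def test_labels_align_with_size(self):
        pmap = ParameterMap(3)
        assert len(pmap.labels()) == pmap.size


class TestDataVector:
    def test_single_region_has_no_imaginary_entries(self, grid_tr2):
        v = np.ones((1, 1, 32), dtype=complex)
        vec, struct = data_vector(CrossSpectra(v, grid_tr2), n_lags=4)
        assert struct.partitions["csd_im"].stop - struct.partitions["csd_im"].start == 0
        assert struct.partitions["csd_re"].stop - struct.partitions["csd_re"].start == 32

    def test_length_formula(self, grid_tr2):
        rng = np.random.default_rng(1)
        n, F, L = 4, 32, 8
        base = rng.normal(size=(n, n, F)) + 1j * rng.normal(size=(n, n, F))
        v = base + np.conj(np.transpose(base, (1, 0, 2)))
        idx = np.arange(n)
        v[idx, idx, :] = np.abs(v[idx, idx, :].real)
        vec, struct = data_vector(CrossSpectra(v, grid_tr2), n_lags=L)
        expected = F * n * (n + 1) // 2 + F * n * (n - 1) // 2 + n * n * (2 * L + 1)
        assert vec.size == expected

    @pytest.mark.parametrize("weighted", [False, True])
    def test_scatter_rebuilds_the_hermitian_csd_exactly(self, grid_tr2, weighted):
        rng = np.random.default_rng(2)
        n, F = 3, 32
        base = rng.normal(size=(n, n, F)) + 1j * rng.normal(size=(n, n, F))
        v = base + np.conj(np.transpose(base, (1, 0, 2)))
        idx = np.arange(n)
        v[idx, idx, :] = np.abs(v[idx, idx, :].real) + 1.0
        csd = CrossSpectra(v, grid_tr2)
        w = rng.uniform(0.5, 2.0, size=F) if weighted else None
        vec, struct = data_vector(csd, n_lags=5, frequency_weights=w)
        back = struct.scatter(vec, grid_tr2)
        assert np.allclose(back.values, v, atol=1e-12)


class TestFreeEnergy:
    def test_zero_residual_bookkeeping(self):
        """With a perfect prediction at the prior mean, F equals the
        hand-computed sum of the three Laplace terms."""
        P = 3
        priors = PriorSpec(np.zeros(P), np.diag([2.0, 1.0, 0.5]))
        y = np.array([1.0, 2.0])
        sigma = 0.5 * np.eye(P)
        lam = 1.7
        hyper = {"all": {"mean": lam}}
        F = free_energy(
            np.zeros(P), sigma, y, priors, hyper, lambda mu: y, {"all": slice(0, 2)}
        )
        LN2PI = np.log(2 * np.pi)
        expected = (
            (0.5 * 2 * lam - 0.5 * 2 * LN2PI)  # likelihood, zero residual
            + (-0.5 * np.log(np.linalg.det(priors.covariance)) - 0.5 * P * LN2PI)
            + 0.5 * (np.log(np.linalg.det(sigma)) + P * LN2PI)
            + (
                -0.5 * (lam - 6.0) ** 2 * 128
                - 0.5 * np.log(2 * np.pi / 128)
            )
        )
        assert F == pytest.approx(expected, abs=1e-10)

    def test_linear_gaussian_evidence(self):
        """For a linear-Gaussian model with fixed noise precision, the
        converged free energy equals the exact log evidence (conjugate
        closed form) to 1e-6."""
        rng = np.random.default_rng(3)
        P, N = 4, 40
        X = rng.normal(size=(N, P))
        theta_true = rng.normal(size=P)
        lam = 2.0
        noise_sd = np.exp(-lam / 2)
        y = X @ theta_true + rng.normal(scale=noise_sd, size=N)
        priors = PriorSpec(np.zeros(P), np.eye(P), hyper_mean=lam, hyper_covariance=1e-8)
        config = InversionConfig(update_hyperparameters=False, max_iterations=50, ftol=1e-8)
        post = variational_laplace(lambda t: X @ t, y, priors, config=config)
        # exact evidence: y ~ N(0, X X' + e^-lam I)
        C = X @ X.T + np.exp(-lam) * np.eye(N)
        sign, logdet = np.linalg.slogdet(C)
        log_evidence = -0.5 * (y @ np.linalg.solve(C, y)) - 0.5 * logdet - 0.5 * N * np.log(2 * np.pi)
        assert post.free_energy == pytest.approx(log_evidence, abs=1e-6)
        # exact conjugate posterior
        S = np.linalg.inv(np.exp(lam) * X.T @ X + np.eye(P))
        m = S @ (np.exp(lam) * X.T @ y)
        assert np.max(np.abs(post.mean - m)) < 1e-4
        assert np.max(np.abs(post.covariance - S)) < 1e-4

    def test_noisier_data_lowers_estimated_log_precision(self):
        """Doubling the observation noise variance in the generating process
        lowers the converged log-precision posterior mean."""
        rng = np.random.default_rng(4)
        P, N = 3, 200
        X = rng.normal(size=(N, P))
        theta = rng.normal(size=P)
        lams = []
        for noise_var in (0.01, 0.02):
            y = X @ theta + rng.normal(scale=np.sqrt(noise_var), size=N)
            priors = PriorSpec(np.zeros(P), 4 * np.eye(P), hyper_mean=4.0,
                               hyper_covariance=16.0)
            post = variational_laplace(lambda t: X @ t, y, priors)
            lams.append(post.hyper_posterior["all"]["mean"])
        assert lams[1] < lams[0]


class TestInvert:
    def test_self_consistency_at_prior_mean(self, hemo4, grid_tr2):
        """Data generated by the prior-mean model are explained without
        moving far from the prior mean, and F increases from start."""
        pmap = ParameterMap(4)
        model0 = pmap.unpack(np.zeros(pmap.size), hemo4, grid_tr2)
        csd = predict_csd(model0)
        post = invert(csd)
        assert np.max(np.abs(post.mean)) < 0.1
        assert post.free_energy >= post.trace[0]

    def test_recovers_benchmark_from_in_family_spectra(
        self, benchmark_conn, hemo4, grid_tr2
    ):
        model = SpectralModel(
            benchmark_conn, hemo4, NoiseSpectralParams.defaults(4), grid_tr2
        )
        post = invert(predict_csd(model))
        A_true = sd.effective_jacobian(benchmark_conn)
        assert sd.rms_error(A_true.ravel(), post.effective_jacobian().ravel()) < 0.05

    def test_free_energy_trace_is_monotone(self, benchmark_posterior):
        assert np.all(np.diff(benchmark_posterior.trace) > 0)

    def test_iterations_within_expected_range(self, benchmark_posterior):
        assert 1 <= benchmark_posterior.n_iterations <= 64

    def test_posterior_covariance_is_symmetric_psd(self, benchmark_posterior):
        C = benchmark_posterior.covariance
        assert np.allclose(C, C.T)
        assert np.min(np.linalg.eigvalsh(C)) > 0

    def test_shuffled_spectra_do_not_fit_better(self, benchmark_run, grid_tr2):
        """Destroying the frequency structure of the data must not yield a
        higher free energy under the true model class (identifiability
        guard)."""
        csd = sd.sample_csd(benchmark_run.bold, grid_tr2)
        post = invert(csd)
        rng = np.random.default_rng(0)
        perm = rng.permutation(grid_tr2.n_bins)
        shuffled = CrossSpectra(csd.values[:, :, perm], grid_tr2)
        post_sh = invert(shuffled)
        assert post_sh.free_energy < post.free_energy

    def test_posterior_serialises_to_json(self, benchmark_posterior, tmp_path):
        import json

        path = tmp_path / "post.json"
        benchmark_posterior.to_json(path)
        doc = json.loads(path.read_text())
        assert len(doc["mean"]) == 34
        assert doc["labels"][0] == "A[1,2]"
        assert np.isfinite(doc["free_energy"])

    def test_dimension_mismatch_raises(self, grid_tr2):
        v = np.ones((2, 2, 32), dtype=complex)
        with pytest.raises(ValueError, match="prior dimension"):
            invert(CrossSpectra(v, grid_tr2), priors=default_priors(3))
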