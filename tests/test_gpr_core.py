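import numpy as np
import pytest

from conical.gpr_core import (
    JITTER,
    FitOptions,
    GPModel,
    KernelParams,
    fit,
    kernel_eval,
    log_marginal_likelihood,
    min_uncertainty,
    predict,
)


def dense_lml_oracle(x, y, params):
    """Independent dense-inverse evaluation of the log marginal likelihood."""
    x = np.atleast_2d(x)
    n = len(y)
    k = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            k[i, j] = kernel_eval(x[i], x[j], params, same_index=(i == j))
    k[np.diag_indices_from(k)] += JITTER
    inv = np.linalg.inv(k)
    _, logdet = np.linalg.slogdet(k)
    return float(-0.5 * y @ inv @ y - 0.5 * logdet - 0.5 * n * np.log(2 * np.pi))


def dense_predict_oracle(model, xq):
    """Brute-force GP mean/variance with explicit inverses."""
    x = model.train_inputs
    n = x.shape[0]
    p = model.params
    k = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            k[i, j] = kernel_eval(x[i], x[j], p, same_index=(i == j))
    k[np.diag_indices_from(k)] += JITTER
    k_star = np.array([kernel_eval(xq, xi, p) for xi in x])
    inv = np.linalg.inv(k)
    mean_s, std_s = model.standardization
    mean = k_star @ inv @ model.train_targets * std_s + mean_s
    var = p.variance + p.noise - k_star @ inv @ k_star
    return float(mean), float(np.sqrt(max(var, 0.0))) * std_s


class TestKernelEval:
    def test_zero_distance_with_noise(self):
        p = KernelParams(2.0, 1.0, 0.5)
        assert kernel_eval(np.zeros(2), np.zeros(2), p, same_index=True) == 2.5

    def test_one_length_scale_away(self):
        p = KernelParams(2.0, 1.0, 0.5)
        val = kernel_eval(np.zeros(1), np.ones(1), p)
        assert val == pytest.approx(2.0 * np.exp(-0.5))

    def test_identical_values_distinct_indices(self):
        p = KernelParams(2.0, 1.0, 0.5)
        a = np.array([1.0, 2.0])
        assert kernel_eval(a, a.copy(), p, same_index=False) == pytest.approx(2.0)

    def test_symmetry_and_bound(self, rng):
        p = KernelParams(1.7, 0.3, 0.2)
        for _ in range(20):
            a, b = rng.normal(size=(2, 4))
            assert kernel_eval(a, b, p) == kernel_eval(b, a, p)
            assert kernel_eval(a, b, p, same_index=True) <= p.variance + p.noise

    def test_positive_params_enforced(self):
        with pytest.raises(ValueError):
            KernelParams(0.0, 1.0, 0.1)


class TestLogMarginalLikelihood:
    def test_single_point_zero_target(self):
        p = KernelParams(2.0, 1.0, 0.5)
        got = log_marginal_likelihood(np.zeros((1, 1)), np.zeros(1), p)
        expected = -0.5 * np.log(2.5 + JITTER) - 0.5 * np.log(2 * np.pi)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_matches_dense_oracle(self, rng):
        x = rng.normal(size=(3, 2))
        y = rng.normal(size=3)
        p = KernelParams(1.3, 0.8, 0.05)
        assert log_marginal_likelihood(x, y, p) == pytest.approx(
            dense_lml_oracle(x, y, p), abs=1e-8
        )

    def test_duplicate_points_regularized_by_noise(self):
        x = np.zeros((5, 2))  # all identical inputs
        y = np.arange(5.0)
        p = KernelParams(1.0, 1.0, 0.1)
        assert np.isfinite(log_marginal_likelihood(x, y, p))


class TestFit:
    def test_noiseless_targets_noise_at_floor(self, rng):
        x = np.linspace(0, 1, 40).reshape(-1, 1)
        y = np.sin(2 * np.pi * x[:, 0])
        model = fit(x, y, FitOptions(restarts=8, seed=0))
        assert model.params.noise < 1e-6

    def test_noise_recovery_within_factor_two(self):
        recovered = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x = rng.uniform(0, 4, size=(200, 1))
            sigma = 0.1
            y = np.sin(x[:, 0]) + rng.normal(scale=sigma, size=200)
            model = fit(x, y, FitOptions(restarts=6, seed=seed))
            # de-standardize the learned noise std
            recovered.append(np.sqrt(model.params.noise) * model.standardization[1])
        mean_rec = np.mean(recovered)
        assert 0.05 < mean_rec < 0.2

    def test_constant_targets_no_crash(self):
        x = np.linspace(0, 1, 10).reshape(-1, 1)
        model = fit(x, np.full(10, 3.0), FitOptions(restarts=2, seed=1))
        mean, _ = predict(model, np.array([0.5]))
        assert mean == pytest.approx(3.0, abs=1e-6)

    def test_beats_coarse_grid_oracle(self, rng):
        x = rng.uniform(-1, 1, size=(15, 1))
        y = x[:, 0] ** 2 + 0.05 * rng.normal(size=15)
        model = fit(x, y, FitOptions(restarts=8, seed=3))
        y_std = (y - y.mean()) / y.std()
        best_grid = -np.inf
        for v in np.logspace(-2, 2, 9):
            for ls in np.logspace(-2, 1, 9):
                for nz in np.logspace(-8, 0, 9):
                    best_grid = max(
                        best_grid,
                        log_marginal_likelihood(x, y_std, KernelParams(v, ls, nz)),
                    )
        fitted = log_marginal_likelihood(x, y_std, model.params)
        assert fitted >= best_grid - 1e-6

    def test_fix_noise_mode(self, rng):
        x = rng.normal(size=(20, 2))
        y = x[:, 0] + x[:, 1] ** 2
        model = fit(x, y, FitOptions(restarts=4, seed=0, fix_noise=1e-10))
        assert model.params.noise == 1e-10

    def test_bound_hits_recorded(self, rng):
        x = rng.normal(size=(10, 1))
        y = rng.normal(size=10)
        model = fit(
            x, y, FitOptions(restarts=4, seed=0, variance_bounds=(0.99, 1.01))
        )
        assert any(h.startswith("variance") for h in model.bound_hits)


class TestPredict:
    def one_point_model(self, noise):
        return GPModel(
            train_inputs=np.zeros((1, 1)),
            train_targets_raw=np.ones(1),
            standardization=(0.0, 1.0),
            params=KernelParams(1.0, 1.0, noise),
        )

    def test_interpolation_noise_to_zero(self):
        model = self.one_point_model(1e-12)
        mean, _ = predict(model, np.zeros(1))
        assert mean == pytest.approx(1.0, abs=1e-9)

    def test_noise_equal_variance_shrinks_half(self):
        model = self.one_point_model(1.0)
        mean, _ = predict(model, np.zeros(1))
        assert mean == pytest.approx(0.5, abs=1e-9)

    def test_far_field_prior(self):
        model = self.one_point_model(0.5)
        mean, std = predict(model, np.array([1e6]))
        assert mean == pytest.approx(0.0, abs=1e-12)
        assert std**2 == pytest.approx(1.5, abs=1e-9)

    def test_matches_dense_oracle(self, rng):
        x = rng.normal(size=(12, 3))
        y = rng.normal(size=12)
        model = fit(x, y, FitOptions(restarts=3, seed=5))
        for _ in range(10):
            xq = rng.normal(size=3)
            mean, std = predict(model, xq)
            mean_o, std_o = dense_predict_oracle(model, xq)
            assert mean == pytest.approx(mean_o, abs=1e-8)
            assert std == pytest.approx(std_o, abs=1e-8)

    def test_adding_point_never_increases_latent_variance(self, rng):
        # noiseless case
        x = rng.normal(size=(8, 2))
        y = rng.normal(size=8)
        params = KernelParams(1.0, 1.0, 1e-10)
        base = GPModel(x, y, (0.0, 1.0), params)
        extended = GPModel(
            np.vstack([x, rng.normal(size=(1, 2))]),
            np.append(y, 0.1),
            (0.0, 1.0),
            params,
        )
        for _ in range(20):
            xq = rng.normal(size=2)
            _, std_base = predict(base, xq, include_noise=False)
            _, std_ext = predict(extended, xq, include_noise=False)
            assert std_ext <= std_base + 1e-7


class TestMinUncertainty:
    def test_noiseless_floor_near_zero(self, rng):
        x = rng.normal(size=(15, 2))
        y = rng.normal(size=15)
        model = GPModel(x, y, (0.0, 1.0), KernelParams(1.0, 1.0, 1e-10))
        # jitter scale: sqrt(noise-at-floor + jitter) ~ 1.4e-5
        assert min_uncertainty(model) <= 2e-5

    def test_single_point_closed_form(self):
        v, nz = 2.0, 0.5
        model = GPModel(
            np.zeros((1, 1)), np.ones(1), (0.0, 1.0), KernelParams(v, 1.0, nz)
        )
        expected = np.sqrt(v * nz / (v + nz))
        assert min_uncertainty(model) == pytest.approx(expected, abs=1e-6)

    def test_monotone_in_noise(self, rng):
        x = rng.normal(size=(10, 2))
        y = rng.normal(size=10)
        floors = [
            min_uncertainty(GPModel(x, y, (0.0, 1.0), KernelParams(1.0, 1.0, nz)))
            for nz in (1e-6, 1e-4, 1e-2, 1.0)
        ]
        assert all(b >= a for a, b in zip(floors, floors[1:]))

    def test_duplicates_do_not_collapse_noisy_floor(self):
        # the central noise-floor claim: with white noise the predicted
        # (observation) variance at a training point stays above sigma_n^2 no
        # matter how many duplicate observations exist, while the latent
        # variance follows the closed form v*nz / (n*v + nz)
        nz, v = 0.09, 1.0
        for n_dup in (1, 5, 50):
            x = np.zeros((n_dup, 1))
            y = np.ones(n_dup)
            model = GPModel(x, y, (0.0, 1.0), KernelParams(v, 1.0, nz))
            _, obs_std = predict(model, np.zeros(1), include_noise=True)
            assert obs_std**2 >= nz - 1e-9
            latent = min_uncertainty(model)
            assert latent**2 == pytest.approx(
                v * nz / (n_dup * v + nz), abs=1e-6
            )


class TestSerialization:
    def test_json_roundtrip(self, rng):
        x = rng.normal(size=(6, 2))
        y = rng.normal(size=6)
        model = fit(x, y, FitOptions(restarts=2, seed=0))
        restored = GPModel.from_json(model.to_json())
        xq = rng.normal(size=2)
        assert predict(restored, xq) == pytest.approx(predict(model, xq), abs=1e-12)
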