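import numpy as np
import pytest
from dataclasses import replace

from indlin import (
    AdaptiveStepConfig,
    DoseEvent,
    EstimationConfig,
    IndLinConfig,
    ObservedDataset,
    PKParameters,
    PredictionCache,
    fit,
    ofv,
    predict,
    reference_solve,
)

from conftest import TIGHT

# fixed-grid, tight-tolerance linearization: the prediction is a smooth
# deterministic function of theta (an adaptive grid re-built per proposal
# adds O(solver error) jitter), which is what mechanism tests need
TIGHT_INDLIN = EstimationConfig(
    backend="indlin",
    indlin=IndLinConfig(epsilon=1e-9, n_max=40, ss=0.01),
    exempt_jacobian_probes=True,
)


def noisy_dataset(theta, dose, times, seed=11, sigma=0.1):
    rng = np.random.default_rng(seed)
    g = reference_solve(theta, dose, times, TIGHT)
    return ObservedDataset(times, g * np.exp(rng.normal(0, sigma, len(times))), dose)


class TestOFV:
    def test_perfect_fit_is_zero(self):
        assert ofv([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_sum_of_squared_residuals(self):
        assert ofv([1.0, 1.0], [0.9, 1.2]) == pytest.approx(0.05)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        y, g = rng.uniform(size=10), rng.uniform(size=10)
        p = rng.permutation(10)
        assert ofv(y, g) == pytest.approx(ofv(y[p], g[p]))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ofv([1.0], [1.0, 2.0])


class TestObservedDataset:
    def test_csv_round_trip(self, theta, dose, times, tmp_path):
        ds = noisy_dataset(theta, dose, times)
        path = tmp_path / "data.csv"
        ds.to_csv(path)
        back = ObservedDataset.from_csv(path, dose)
        assert np.allclose(back.times, ds.times)
        assert np.allclose(back.concentrations, ds.concentrations)

    def test_from_csv_sorts_rows(self, theta, dose, times, tmp_path):
        ds = noisy_dataset(theta, dose, times)
        path = tmp_path / "shuffled.csv"
        import pandas as pd

        df = pd.DataFrame({"time_h": ds.times, "conc_mg_L": ds.concentrations})
        df.sample(frac=1, random_state=1).to_csv(path, index=False)
        back = ObservedDataset.from_csv(path, dose)
        assert np.allclose(back.times, ds.times)

    def test_missing_column_rejected(self, dose, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("time_h,foo\n1,2\n")
        with pytest.raises(ValueError):
            ObservedDataset.from_csv(path, dose)

    def test_nonpositive_concentration_rejected(self, dose):
        with pytest.raises(ValueError):
            ObservedDataset(np.array([1.0, 2, 3, 4]), np.array([1.0, -1, 1, 1]), dose)


class TestPredict:
    def test_cold_cache_equals_cold_start(self, theta, dose, times):
        cfg = EstimationConfig(backend="indlin")
        no_cache = predict(theta, times, dose, cfg, cache=None)
        cache = PredictionCache()
        with_cache = predict(theta, times, dose, cfg, cache=cache)
        assert np.array_equal(no_cache, with_cache)
        assert cache.n_warm_starts == 0

    def test_primed_cache_converges_in_one_iteration(self, theta, dose, times):
        cfg = EstimationConfig(backend="indlin")
        cache = PredictionCache()
        first = predict(theta, times, dose, cfg, cache=cache)
        before = cache.total_indlin_iterations
        second = predict(theta, times, dose, cfg, cache=cache)
        assert cache.total_indlin_iterations - before == 1
        assert np.allclose(second, first, rtol=10 * cfg.indlin.epsilon)

    def test_backends_agree_on_the_nominal_problem(self, theta, dose, times, tight_reference):
        # second-order stepping against a tight RK oracle
        cfg = EstimationConfig(
            backend="indlin",
            indlin=IndLinConfig(epsilon=1e-9, n_max=40, ss=0.01, plugin_eval="midpoint"),
        )
        c = predict(theta, times, dose, cfg)
        assert np.max(np.abs(c - tight_reference) / tight_reference) < 1e-4
        # the default first-order rule at the same step is within its own O(ss) error
        cfg_left = EstimationConfig(
            backend="indlin", indlin=IndLinConfig(epsilon=1e-9, n_max=40, ss=0.01)
        )
        c_left = predict(theta, times, dose, cfg_left)
        assert np.max(np.abs(c_left - tight_reference) / tight_reference) < 5e-3


class TestFit:
    def test_zero_residual_fixed_point(self, theta, dose, times):
        # noise-free data generated by the same backend, started at truth
        cfg = EstimationConfig(backend="reference")
        g = reference_solve(theta, dose, times)
        ds = ObservedDataset(times, g, dose)
        res = fit(ds, cfg)
        assert res.ofv < 1e-10
        assert np.allclose(res.theta_hat.as_array(), theta.as_array(), rtol=1e-6)

    @pytest.mark.parametrize("backend_cfg", ["reference", "indlin_tight"])
    def test_noise_free_identifiability_from_perturbed_start(
        self, theta, dose, times, backend_cfg
    ):
        cfg = (
            EstimationConfig(backend="reference", reference=TIGHT)
            if backend_cfg == "reference"
            else TIGHT_INDLIN
        )
        g = predict(theta, times, dose, cfg)
        ds = ObservedDataset(times, g, dose)
        start = PKParameters.from_array(1.2 * theta.as_array())
        res = fit(ds, replace(cfg, theta0=start))
        assert np.allclose(res.theta_hat.as_array(), theta.as_array(), rtol=1e-4)

    def test_descent_property(self, theta, dose, times):
        ds = noisy_dataset(theta, dose, times, seed=5)
        cfg = EstimationConfig(backend="reference")
        res = fit(ds, cfg)
        start_ofv = ofv(ds.concentrations, reference_solve(theta, dose, times))
        assert res.ofv <= start_ofv

    def test_fit_invariant_to_row_order(self, theta, dose, times, tmp_path):
        ds = noisy_dataset(theta, dose, times, seed=9)
        import pandas as pd

        df = pd.DataFrame({"time_h": ds.times, "conc_mg_L": ds.concentrations})
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        df.to_csv(p1, index=False)
        df.sample(frac=1, random_state=2).to_csv(p2, index=False)
        cfg = EstimationConfig(backend="reference")
        r1 = fit(ObservedDataset.from_csv(p1, dose), cfg)
        r2 = fit(ObservedDataset.from_csv(p2, dose), cfg)
        assert np.array_equal(r1.theta_hat.as_array(), r2.theta_hat.as_array())

    def test_optimizer_failure_is_reported_not_raised(self, theta, dose, times):
        ds = noisy_dataset(theta, dose, times, seed=3)
        cfg = EstimationConfig(backend="reference", max_nfev=3)
        res = fit(ds, cfg)
        assert res.n_function_evals <= 3 or not res.success

    def test_smart_update_changes_speed_not_answers(self, theta, dose, times):
        ds = noisy_dataset(theta, dose, times, seed=21)
        smart = TIGHT_INDLIN
        cold = replace(TIGHT_INDLIN, smart_update=False)
        r_smart, r_cold = fit(ds, smart), fit(ds, cold)
        rel = np.abs(r_smart.theta_hat.as_array() - r_cold.theta_hat.as_array()) / np.abs(
            r_cold.theta_hat.as_array()
        )
        assert np.max(rel) < 1e-3
        assert r_smart.total_indlin_iterations < r_cold.total_indlin_iterations

    def test_monte_carlo_unbiasedness_of_the_reference_fit(self, theta, dose, times):
        # 40 noisy datasets at sigma=0.1: the mean estimate of each
        # parameter stays within 3 standard errors of the truth
        rels = []
        cfg = EstimationConfig(backend="reference")
        for seed in range(40):
            ds = noisy_dataset(theta, dose, times, seed=100 + seed)
            res = fit(ds, cfg)
            rels.append((res.theta_hat.as_array() - theta.as_array()) / theta.as_array())
        rels = np.asarray(rels)
        mean = rels.mean(axis=0)
        se = rels.std(axis=0, ddof=1) / np.sqrt(len(rels))
        assert np.all(np.abs(mean) <= 3 * se + 1e-12)
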