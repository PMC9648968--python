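"""Likelihood construction, curation transforms, fitting and profile intervals."""

import numpy as np
import pytest

from burstfish import (
    MatureModelSpec,
    MatureScale,
    NascentModelSpec,
    NascentScale,
    ObservedDataset,
    OptimizerConfig,
    RateParams,
    SearchSpace,
    SimConfig,
    convolve_pmf,
    curate_fusion,
    curate_rejection,
    fit,
    model_pmf,
    negative_log_likelihood,
    profile_likelihood_ci,
    simulate_mature_cells,
    telegraph_pmf,
)
from burstfish._exceptions import DegenerateDataWarning, InvalidParameterError

SCALE = MatureScale(d=1.0)
FAST = OptimizerConfig(popsize=8, tol=1e-4)


class TestNegativeLogLikelihood:
    def test_certain_observation_gives_zero(self):
        # rho = 0 puts all model mass on zero counts
        data = ObservedDataset("mature", [0])
        assert negative_log_likelihood(data, RateParams(1, 1, 0), SCALE) == 0.0

    def test_matches_hand_computed_sum(self):
        params = RateParams(2, 3, 15)
        probs = telegraph_pmf(MatureModelSpec(params, 1.0)).probs
        values = np.array([0, 3, 7, 3])
        data = ObservedDataset("mature", values)
        expect = -np.log(probs[values]).sum()
        assert abs(negative_log_likelihood(data, params, SCALE) - expect) < 1e-9

    def test_permutation_invariance_and_histogram_identity(self):
        rng = np.random.default_rng(0)
        values = rng.poisson(8, size=500)
        params = RateParams(2, 1, 12)
        a = negative_log_likelihood(ObservedDataset("mature", values), params, SCALE)
        b = negative_log_likelihood(
            ObservedDataset("mature", rng.permutation(values)), params, SCALE
        )
        assert abs(a - b) < 1e-9

    def test_two_copy_independent_equals_self_convolution(self):
        params = RateParams(2, 3, 15)
        single = telegraph_pmf(MatureModelSpec(params, 1.0))
        expect = convolve_pmf(single, single).probs
        got = model_pmf(params, "mature", SCALE, copy_mode="independent")
        assert np.allclose(got[: len(expect)], expect)

    def test_empty_data_rejected(self):
        with pytest.raises(InvalidParameterError):
            ObservedDataset("mature", [])

    def test_likelihood_concentrates_at_truth(self):
        truth = RateParams(5, 5, 40)
        wins = 0
        for seed in range(6):
            m = simulate_mature_cells(MatureModelSpec(truth, 1.0), SimConfig(5000, seed=seed))
            data = ObservedDataset("mature", m)
            doubled = RateParams(10, 10, 80)  # same fON, doubled speed
            perturbed = RateParams(5, 5, 80)
            wins += negative_log_likelihood(data, truth, SCALE) < min(
                negative_log_likelihood(data, doubled, SCALE),
                negative_log_likelihood(data, perturbed, SCALE),
            )
        assert wins >= 5


class TestFusion:
    def test_k1_is_identity(self):
        probs = np.array([0.1, 0.2, 0.7])
        values = np.array([0, 1, 2])
        p, v = curate_fusion(probs, values, 1)
        assert np.array_equal(p, probs) and np.array_equal(v, values)

    def test_k4_merges_low_bins(self):
        probs = np.array([0.1, 0.1, 0.1, 0.1, 0.6])
        values = np.array([0, 1, 2, 3, 4])
        p, v = curate_fusion(probs, values, 4)
        assert np.allclose(p, [0.4, 0.6])
        assert v.tolist() == [0, 0, 0, 0, 1]

    def test_mass_conserved(self):
        rng = np.random.default_rng(1)
        probs = rng.dirichlet(np.ones(12))
        for k in (2, 5, 11):
            p, _ = curate_fusion(probs, np.arange(12), k)
            assert abs(p.sum() - 1) < 1e-12

    def test_k_beyond_support_raises(self):
        with pytest.raises(InvalidParameterError):
            curate_fusion(np.array([0.5, 0.5]), np.array([0]), 3)


class TestRejection:
    def test_conditional_renormalization(self):
        p, v = curate_rejection(np.array([0.25, 0.25, 0.5]), np.array([0, 1, 2, 2]), 2)
        assert np.allclose(p, [1.0])
        assert v.tolist() == [0, 0]

    def test_k1_drops_only_zero_bin(self):
        probs = np.array([0.3, 0.3, 0.4])
        p, v = curate_rejection(probs, np.array([0, 1, 2]), 1)
        assert abs(p.sum() - 1) < 1e-12
        assert np.allclose(p, [0.3 / 0.7, 0.4 / 0.7])
        assert v.tolist() == [0, 1]

    def test_all_rejected_raises(self):
        with pytest.raises(InvalidParameterError):
            curate_rejection(np.array([0.5, 0.5]), np.array([0, 0]), 1)


class TestFit:
    def test_recovers_rates_from_mature_data(self):
        truth = RateParams(7.5, 7.5, 50)
        m = simulate_mature_cells(MatureModelSpec(truth, 1.0), SimConfig(10_000, seed=11))
        res = fit(ObservedDataset("mature", m), SCALE, optimizer=OptimizerConfig(seed=1))
        assert abs(res.theta_star.rho - 50) / 50 < 0.15
        assert abs(res.derived["fraction_on"] - 0.5) < 0.07
        assert np.isfinite(res.nll) and res.iterations > 0

    def test_all_zero_data_flags_degenerate(self):
        data = ObservedDataset("mature", np.zeros(50, dtype=int))
        with pytest.warns(DegenerateDataWarning):
            res = fit(data, SCALE, optimizer=FAST)
        assert res.degenerate
        assert res.theta_star.rho < 1.0  # pinned near the lower bound

    def test_result_serializes(self, tmp_path):
        data = ObservedDataset("mature", np.array([1, 2, 3, 2, 1]))
        res = fit(data, SCALE, optimizer=FAST)
        res.to_json(tmp_path / "fit.json", config={"kind": "mature"})
        import json

        obj = json.loads((tmp_path / "fit.json").read_text())
        assert {"sigma_on", "sigma_off", "rho", "nll", "derived", "config"} <= set(obj)


class TestProfileLikelihoodCI:
    @pytest.fixture(scope="class")
    def fitted(self):
        truth = RateParams(7.5, 7.5, 50)
        m = simulate_mature_cells(MatureModelSpec(truth, 1.0), SimConfig(4000, seed=21))
        data = ObservedDataset("mature", m)
        return data, fit(data, SCALE, optimizer=OptimizerConfig(seed=2))

    def test_interval_contains_estimate(self, fitted):
        data, res = fitted
        ci = profile_likelihood_ci(data, res, "rho", SCALE, n_grid=21)
        assert ci["lower"] <= res.theta_star.rho <= ci["upper"]
        assert not ci["lower_at_bound"] and not ci["upper_at_bound"]

    def test_width_shrinks_with_sample_size(self, fitted):
        data_small, res_small = fitted
        truth = RateParams(7.5, 7.5, 50)
        m = simulate_mature_cells(MatureModelSpec(truth, 1.0), SimConfig(16_000, seed=21))
        data_big = ObservedDataset("mature", m)
        res_big = fit(data_big, SCALE, optimizer=OptimizerConfig(seed=2))
        ci_s = profile_likelihood_ci(data_small, res_small, "rho", SCALE, n_grid=21)
        ci_b = profile_likelihood_ci(data_big, res_big, "rho", SCALE, n_grid=21)
        assert (ci_b["upper"] - ci_b["lower"]) < (ci_s["upper"] - ci_s["lower"])

    def test_unknown_parameter_rejected(self, fitted):
        data, res = fitted
        with pytest.raises(InvalidParameterError):
            profile_likelihood_ci(data, res, "d", SCALE)


def test_search_space_validation():
    with pytest.raises(InvalidParameterError):
        SearchSpace(lower=(1, 1, 1), upper=(0.5, 2, 2))
    s = SearchSpace()
    assert np.all(np.asarray(s.clip(np.array([500.0, -3.0, 100.0]))) <= s.upper)


def test_nascent_scale_requires_matching_kind():
    with pytest.raises(InvalidParameterError):
        model_pmf(RateParams(1, 1, 5), "mature", NascentScale())
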