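import numpy as np
import pytest
import statsmodels.api as sm

from gutmr.estimators import (
    MIN_SNPS,
    Z95,
    all_estimates,
    beta_to_or,
    egger,
    ivw,
    wald_ratio,
    weighted_median,
    weighted_mode,
)
from gutmr.instruments import InsufficientInstrumentsError
from gutmr.simulate import SimulationConfig, simulate_two_sample
from gutmr.harmonize import harmonize_pair

from conftest import make_hset


def random_hset(seed, n=12):
    rng = np.random.default_rng(seed)
    gamma = rng.uniform(0.05, 0.3, n)
    se_G = rng.uniform(0.01, 0.05, n)
    Gamma = 0.3 * gamma + rng.normal(0, se_G)
    return make_hset(gamma, Gamma, se_G)


class TestWaldRatio:
    def test_point_and_se(self):
        est = wald_ratio(0.1, 0.05, 0.01)
        assert est.beta == pytest.approx(0.5)
        assert est.se == pytest.approx(0.1)
        assert est.nsnp == 1

    def test_zero_outcome_effect(self):
        assert wald_ratio(0.1, 0.0, 0.01).beta == 0.0

    def test_zero_gamma_rejected(self):
        with pytest.raises(ZeroDivisionError):
            wald_ratio(0.0, 0.05, 0.01)

    def test_delta_se_matches_monte_carlo_sd(self):
        # strong instrument: first-order SE ~ SD of simulated ratios
        rng = np.random.default_rng(1)
        gamma, se_G = 0.2, 0.01
        ratios = (0.1 + rng.normal(0, se_G, 200_000)) / gamma
        assert se_G / gamma == pytest.approx(ratios.std(), rel=0.05)


class TestIVW:
    def test_duplicated_ratio_recovers_it(self):
        est = ivw(make_hset([0.1, 0.1], [0.05, 0.05], [0.1, 0.1]))
        assert est.beta == pytest.approx(0.5)

    def test_closed_form_two_snp_example(self):
        hset = make_hset([0.2, 0.1], [0.1, 0.05], [0.1, 0.1])
        est = ivw(hset, mode="fixed")
        assert est.beta == pytest.approx(0.5)
        assert est.se == pytest.approx(np.sqrt(1 / 5), abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_wls_through_origin(self, seed):
        hset = random_hset(seed)
        w = 1 / hset.se_Gamma**2
        fit = sm.WLS(hset.Gamma, hset.gamma[:, None], weights=w).fit()
        est = ivw(hset, mode="fixed")
        assert est.beta == pytest.approx(float(fit.params[0]), abs=1e-10)
        unscaled_se = float(fit.bse[0]) / np.sqrt(float(fit.scale))
        assert est.se == pytest.approx(unscaled_se, abs=1e-10)

    def test_random_effects_se_never_below_fixed(self):
        for seed in range(5):
            hset = random_hset(seed)
            assert ivw(hset).se >= ivw(hset, mode="fixed").se - 1e-15

    def test_single_snp_rejected_with_wald_hint(self):
        with pytest.raises(InsufficientInstrumentsError, match="wald"):
            ivw(make_hset([0.1], [0.05], [0.1]))

    def test_degenerates_to_wald_on_pair_of_identical_snps(self):
        hset = make_hset([0.2, 0.2], [0.1, 0.1], [0.05, 0.05])
        assert ivw(hset).beta == pytest.approx(wald_ratio(0.2, 0.1, 0.05).beta)


class TestEgger:
    def test_exact_fit_recovers_intercept_and_slope(self):
        gamma = np.array([0.1, 0.2, 0.3])
        Gamma = 0.02 + 0.3 * gamma
        est = egger(make_hset(gamma, Gamma, [0.05] * 3))
        assert est.egger_intercept == pytest.approx(0.02, abs=1e-12)
        assert est.beta == pytest.approx(0.3, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_closed_form_wls(self, seed):
        hset = random_hset(seed)
        w = 1 / hset.se_Gamma**2
        X = sm.add_constant(hset.gamma)
        fit = sm.WLS(hset.Gamma, X, weights=w).fit()
        est = egger(hset)
        assert est.egger_intercept == pytest.approx(float(fit.params[0]), abs=1e-10)
        assert est.beta == pytest.approx(float(fit.params[1]), abs=1e-10)

    def test_gamma_orientation_invariance(self):
        # flipping the sign of (gamma, Gamma) rows must not change the fit
        hset = random_hset(3)
        flipped = make_hset(-hset.gamma, -hset.Gamma, hset.se_Gamma)
        a, b = egger(hset), egger(flipped)
        assert a.beta == pytest.approx(b.beta, abs=1e-12)
        assert a.egger_intercept == pytest.approx(b.egger_intercept, abs=1e-12)

    def test_min_snp_rule(self):
        with pytest.raises(InsufficientInstrumentsError):
            egger(make_hset([0.1, 0.2], [0.05, 0.06], [0.05, 0.05]))


class TestWeightedMedian:
    def test_interpolation_formula_on_three_ratios(self):
        hset = make_hset([0.1, 0.1, 0.1], [0.01, 0.02, 0.09], [0.05, 0.05, 0.05])
        est = weighted_median(hset, bootstrap_reps=200, seed=0)
        assert est.beta == pytest.approx(0.2, abs=1e-12)

    def test_identical_ratios_returned_with_small_se(self):
        hset = make_hset([0.1, 0.2, 0.3], [0.05, 0.10, 0.15], [0.03, 0.03, 0.03],
                         se_gamma=[1e-6] * 3)
        est = weighted_median(hset, bootstrap_reps=200, seed=0)
        assert est.beta == pytest.approx(0.5, abs=1e-12)
        assert est.se < 0.5

    def test_bootstrap_se_is_seed_deterministic(self):
        hset = random_hset(2)
        a = weighted_median(hset, bootstrap_reps=300, seed=7)
        b = weighted_median(hset, bootstrap_reps=300, seed=7)
        assert a.se == b.se


class TestWeightedMode:
    def test_finds_the_cluster_not_the_mean(self):
        ratios = np.array([0.3, 0.29, 0.31, 0.3, 0.28, 0.32, 0.3, 1.5, 1.48, 1.52])
        gamma = np.full(10, 0.2)
        hset = make_hset(gamma, ratios * gamma, np.full(10, 0.02))
        est = weighted_mode(hset, bootstrap_reps=100, seed=0)
        assert abs(est.beta - 0.3) < 0.05
        assert abs(est.beta - ratios.mean()) > 0.2

    def test_all_equal_ratios(self):
        hset = make_hset([0.1, 0.2, 0.4], [0.05, 0.10, 0.20], [0.02, 0.02, 0.02])
        est = weighted_mode(hset, bootstrap_reps=100, seed=0)
        assert est.beta == pytest.approx(0.5, abs=1e-9)

    def test_symmetric_unimodal_mode_near_median(self):
        rng = np.random.default_rng(4)
        gamma = rng.uniform(0.1, 0.3, 30)
        se_G = np.full(30, 0.01)
        Gamma = 0.4 * gamma + rng.normal(0, 0.01, 30)
        hset = make_hset(gamma, Gamma, se_G)
        mode_est = weighted_mode(hset, bootstrap_reps=100, seed=0)
        med_est = weighted_median(hset, bootstrap_reps=100, seed=0)
        assert mode_est.beta == pytest.approx(med_est.beta, abs=0.05)


class TestOrConversion:
    def test_null_beta_gives_unit_or(self):
        assert beta_to_or(0.0, 0.1) == pytest.approx((1.0, np.exp(-Z95 * 0.1), np.exp(Z95 * 0.1)))

    def test_log_two(self):
        or_value, lo, hi = beta_to_or(np.log(2), 0.1)
        assert or_value == pytest.approx(2.000, abs=5e-4)
        assert lo == pytest.approx(1.644, abs=5e-4)
        assert hi == pytest.approx(2.433, abs=5e-4)

    def test_ci_straddles_or(self):
        for beta in (-1.0, 0.0, 2.5):
            or_value, lo, hi = beta_to_or(beta, 0.3)
            assert lo < or_value < hi


class TestEstimatorInvariants:
    def test_rescaling_transformation_law(self):
        # gamma, Gamma scaled by c > 0 with SEs untouched: ratio-based and
        # regression slopes are unchanged; the Egger intercept scales by c
        hset = random_hset(8)
        c = 3.7
        scaled = make_hset(c * hset.gamma, c * hset.Gamma, hset.se_Gamma,
                           se_gamma=hset.se_gamma)
        assert ivw(scaled, mode="fixed").beta == pytest.approx(ivw(hset, mode="fixed").beta)
        assert weighted_median(scaled, 100, 0).beta == pytest.approx(
            weighted_median(hset, 100, 0).beta, abs=1e-9)
        e0, e1 = egger(hset), egger(scaled)
        assert e1.beta == pytest.approx(e0.beta, abs=1e-9)
        assert e1.egger_intercept == pytest.approx(c * e0.egger_intercept, abs=1e-9)

    def test_sign_convention(self):
        hset = random_hset(9)
        neg = make_hset(hset.gamma, -hset.Gamma, hset.se_Gamma, se_gamma=hset.se_gamma)
        assert ivw(neg).beta == pytest.approx(-ivw(hset).beta)
        assert egger(neg).beta == pytest.approx(-egger(hset).beta)
        assert weighted_median(neg, 100, 0).beta == pytest.approx(
            -weighted_median(hset, 100, 0).beta, abs=1e-9)

    def test_parameter_recovery_all_estimators(self):
        # no pleiotropy, strong instruments: every estimator's mean estimate
        # sits within 3 Monte-Carlo SEs of the true effect
        reps = 120
        true_beta = 0.25
        results = {"ivw": [], "egger": [], "weighted_median": [], "weighted_mode": []}
        for s in range(reps):
            cfg = SimulationConfig(n_variants=30, n_instruments=30,
                                   causal_effect=true_beta, seed=10_000 + s,
                                   palindromic_fraction=0.0)
            data = simulate_two_sample(cfg)
            hset = harmonize_pair(data.exposure, data.outcome)
            results["ivw"].append(ivw(hset).beta)
            results["egger"].append(egger(hset).beta)
            results["weighted_median"].append(
                weighted_median(hset, bootstrap_reps=50, seed=s).beta)
            results["weighted_mode"].append(
                weighted_mode(hset, bootstrap_reps=50, seed=s).beta)
        for method, vals in results.items():
            vals = np.asarray(vals)
            mc_se = vals.std(ddof=1) / np.sqrt(reps)
            assert abs(vals.mean() - true_beta) < 3 * mc_se + 0.005, method

    def test_all_estimates_respects_min_snp_rules(self):
        two = make_hset([0.1, 0.2], [0.05, 0.1], [0.05, 0.05])
        methods = {e.method for e in all_estimates(two)}
        assert methods == {"ivw"}
        one = make_hset([0.1], [0.05], [0.05])
        assert {e.method for e in all_estimates(one)} == {"wald"}
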