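"""MR estimators against independent weighted-least-squares oracles and
their degenerate/analytic cases."""

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats

from epimr import (
    EstimationError,
    egger,
    heterogeneity,
    ivw,
    leave_one_out,
    mr_presso,
    rucker_select,
    steiger_directionality,
    wald_ratios,
    weighted_median,
)
from epimr.gwas_io import harmonized_from_arrays
from epimr.simulate import SimulationConfig, asymptotic_draws, simulate_two_sample
from epimr import harmonize


def _random_instance(rng, J=12):
    g = rng.uniform(0.03, 0.2, J) * rng.choice([-1, 1], J)
    seg = rng.uniform(0.004, 0.02, J)
    seG = rng.uniform(0.005, 0.03, J)
    G = 0.3 * g + rng.normal(0, seG)
    return harmonized_from_arrays(g, seg, G, seG, n_exp=30_000, n_out=30_000)


class TestWaldRatios:
    def test_arithmetic(self):
        h = harmonized_from_arrays([0.1], [0.01], [0.02], [0.005],
                                   n_exp=1000, n_out=1000)
        (est,) = wald_ratios(h)
        assert est.beta == pytest.approx(0.2)
        assert est.se == pytest.approx(0.05)

    def test_sign(self):
        h = harmonized_from_arrays([-0.1], [0.01], [0.02], [0.005],
                                   n_exp=1000, n_out=1000)
        (est,) = wald_ratios(h)
        assert est.beta == pytest.approx(-0.2)

    def test_vector_matches_scalar_loop(self, rng):
        h = _random_instance(rng, J=5)
        ests = wald_ratios(h)
        r = h.retained
        for est, (_, row) in zip(ests, r.iterrows()):
            assert est.beta == pytest.approx(row.beta_out / row.beta_exp)
            assert est.se == pytest.approx(row.se_out / abs(row.beta_exp))

    def test_zero_exposure_beta_excluded(self):
        h = harmonized_from_arrays([0.0, 0.1], [0.01, 0.01], [0.02, 0.02],
                                   [0.005, 0.005], n_exp=1000, n_out=1000)
        with pytest.warns(UserWarning, match="beta_exp = 0"):
            ests = wald_ratios(h)
        assert len(ests) == 1


class TestIVW:
    def test_single_snp_equals_wald_ratio(self):
        h = harmonized_from_arrays([0.1], [0.01], [0.02], [0.005],
                                   n_exp=1000, n_out=1000)
        est = ivw(h, _allow_single=True)
        assert est.beta == pytest.approx(0.2)
        with pytest.raises(EstimationError, match="wald"):
            ivw(h)

    def test_perfect_proportionality(self):
        g = np.array([0.05, 0.08, 0.1, 0.12, 0.15])
        h = harmonized_from_arrays(g, np.full(5, 0.01), 0.5 * g, np.full(5, 0.01),
                                   n_exp=1000, n_out=1000)
        est = ivw(h)
        assert est.beta == pytest.approx(0.5, abs=1e-14)
        assert est.overdispersion == pytest.approx(0.0, abs=1e-20)

    def test_matches_wls_oracle_on_random_instances(self, rng):
        """IVW equals a statsmodels WLS through the origin to 1e-10."""
        for _ in range(25):
            h = _random_instance(rng)
            g, seg, G, seG = h.arrays()
            fit = sm.WLS(G, g[:, None], weights=1.0 / seG**2).fit()
            est = ivw(h, random_effects=False)
            assert est.beta == pytest.approx(fit.params[0], rel=1e-10)

    def test_random_effects_floor_never_beats_fixed(self, rng):
        h = _random_instance(rng)
        assert ivw(h, random_effects=True).se >= ivw(h, random_effects=False).se


class TestEgger:
    def test_exact_line_recovered(self):
        g = np.array([0.05, 0.08, 0.1, 0.12])
        G = 0.03 + 0.4 * g
        h = harmonized_from_arrays(g, np.full(4, 0.01), G, np.full(4, 0.01),
                                   n_exp=1000, n_out=1000)
        slope, intercept = egger(h)
        assert slope.beta == pytest.approx(0.4, abs=1e-12)
        assert slope.intercept == pytest.approx(0.03, abs=1e-12)
        het = heterogeneity(h)
        assert het.q_prime == pytest.approx(0.0, abs=1e-20)

    def test_two_snps_insufficient(self):
        h = harmonized_from_arrays([0.1, 0.2], [0.01] * 2, [0.02, 0.04], [0.01] * 2,
                                   n_exp=1000, n_out=1000)
        with pytest.raises(EstimationError, match="insufficient"):
            egger(h)

    def test_matches_wls_oracle_with_same_orientation(self, rng):
        """Slope/intercept equal statsmodels WLS with intercept after
        orienting all gamma >= 0."""
        for _ in range(25):
            h = _random_instance(rng, J=10)
            g, seg, G, seG = h.arrays()
            sign = np.where(g < 0, -1.0, 1.0)
            go, Go = g * sign, G * sign
            X = sm.add_constant(go)
            fit = sm.WLS(Go, X, weights=1.0 / seG**2).fit()
            slope, _ = egger(h, random_effects=False)
            assert slope.beta == pytest.approx(fit.params[1], rel=1e-10)
            assert slope.intercept == pytest.approx(fit.params[0], rel=1e-10, abs=1e-12)

    def test_intercept_t_inference(self, rng):
        h = _random_instance(rng, J=8)
        slope, intercept = egger(h)
        t = intercept.beta / intercept.se
        assert intercept.pvalue == pytest.approx(2 * stats.t.sf(abs(t), 6), rel=1e-12)


class TestWeightedMedian:
    def test_constant_ratios_give_constant(self):
        g = np.array([0.05, 0.1, 0.2, 0.4])
        h = harmonized_from_arrays(g, np.full(4, 0.01), 0.7 * g,
                                   np.array([0.01, 0.02, 0.01, 0.03]),
                                   n_exp=1000, n_out=1000)
        est = weighted_median(h, n_boot=200, seed=1)
        assert est.beta == pytest.approx(0.7, abs=1e-12)

    def test_equal_weights_odd_j_is_middle_order_statistic(self):
        g = np.full(5, 0.1)
        ratios = np.array([0.1, 0.5, 0.3, 0.9, 0.7])
        h = harmonized_from_arrays(g, np.full(5, 0.01), ratios * g, np.full(5, 0.01),
                                   n_exp=1000, n_out=1000)
        est = weighted_median(h, n_boot=200, seed=1)
        assert est.beta == pytest.approx(0.5)

    def test_interpolation_definition_on_four_snps(self):
        """Point estimate equals a direct evaluation of the cumulative
        weight interpolation."""
        g = np.array([0.1, 0.1, 0.1, 0.1])
        G = np.array([0.01, 0.03, 0.05, 0.09])
        seG = np.array([0.01, 0.005, 0.02, 0.01])
        h = harmonized_from_arrays(g, np.full(4, 0.001), G, seG,
                                   n_exp=1000, n_out=1000)
        ratios = G / g
        w = (np.abs(g) / seG) ** 2
        order = np.argsort(ratios)
        b, wn = ratios[order], w[order] / w.sum()
        cum = np.cumsum(wn) - wn / 2
        expected = np.interp(0.5, cum, b)
        est = weighted_median(h, n_boot=200, seed=1)
        assert est.beta == pytest.approx(expected, rel=1e-12)

    def test_equals_ivw_when_ratios_coincide(self, rng):
        g = rng.uniform(0.05, 0.2, 6)
        h = harmonized_from_arrays(g, np.full(6, 0.01), 0.25 * g, np.full(6, 0.01),
                                   n_exp=1000, n_out=1000)
        assert weighted_median(h, n_boot=200, seed=1).beta == pytest.approx(
            ivw(h).beta, abs=1e-12)

    def test_small_bootstrap_warns(self, proportional_harmonized):
        with pytest.warns(UserWarning, match="n_boot"):
            weighted_median(proportional_harmonized, n_boot=50, seed=1)


class TestHeterogeneityAndRucker:
    def test_exact_proportional_data(self, proportional_harmonized):
        het = heterogeneity(proportional_harmonized)
        assert het.q == pytest.approx(0.0, abs=1e-20)
        assert het.q_prime == pytest.approx(0.0, abs=1e-20)
        assert het.p_diff == pytest.approx(1.0)

    def test_qprime_never_exceeds_q(self, rng):
        for _ in range(20):
            het = heterogeneity(_random_instance(rng))
            assert het.q_prime <= het.q + 1e-12

    def test_q_matches_direct_summation(self, rng):
        h = _random_instance(rng, J=4)
        g, seg, G, seG = h.arrays()
        w = 1 / seG**2
        b = np.sum(w * g * G) / np.sum(w * g * g)
        q = np.sum(w * (G - b * g) ** 2)
        assert heterogeneity(h).q == pytest.approx(q, rel=1e-12)

    def test_rucker_rule_requires_both_conditions(self, rng):
        # homogeneous, no pleiotropy: IVW should be retained
        h = _random_instance(rng)
        sel = rucker_select(h)
        assert sel.chosen_method in ("IVW", "MR-Egger")
        assert (sel.chosen_method == "MR-Egger") == (
            sel.p_diff < 0.05 and sel.intercept_p < 0.1)

    def test_rucker_detects_planted_directional_pleiotropy(self):
        """Directional pleiotropy (30% invalid, mean alpha > 0) makes
        MR-Egger the majority choice over seeded replicates.  The instrument
        is kidney-instrument-sized (J = 100): the intercept test that gates
        the Rücker switch needs that many SNPs for adequate power because
        its SE is inflated by the pleiotropy-driven overdispersion."""
        chosen = []
        for seed in range(40):
            cfg = SimulationConfig(J=100, beta_true=0.1, prop_invalid=0.3,
                                   mean_alpha=0.02, sd_alpha=0.005)
            g, seg, G, seG = asymptotic_draws(cfg, 1, np.random.default_rng(seed))
            h = harmonized_from_arrays(g[0], seg[0], G[0], seG[0],
                                       n_exp=50_000, n_out=50_000)
            chosen.append(rucker_select(h).chosen_method)
        assert chosen.count("MR-Egger") > len(chosen) / 2


class TestScaleInvariance:
    def test_exposure_rescaling(self, rng):
        """gamma -> c * gamma rescales all causal estimates by 1/c and leaves
        Q, Q', and p-values unchanged."""
        h = _random_instance(rng)
        g, seg, G, seG = h.arrays()
        c = 3.7
        h2 = harmonized_from_arrays(c * g, c * seg, G, seG, n_exp=30_000, n_out=30_000)
        for fn in (lambda x: ivw(x), lambda x: egger(x)[0]):
            e1, e2 = fn(h), fn(h2)
            assert e2.beta == pytest.approx(e1.beta / c, rel=1e-10)
            assert e2.pvalue == pytest.approx(e1.pvalue, rel=1e-9)
        het1, het2 = heterogeneity(h), heterogeneity(h2)
        assert het2.q == pytest.approx(het1.q, rel=1e-10)
        assert het2.q_prime == pytest.approx(het1.q_prime, rel=1e-10)


class TestPresso:
    def _planted_outlier(self, seed, J=21, shift=10.0):
        rng = np.random.default_rng(seed)
        g = rng.uniform(0.05, 0.15, J)
        seg = np.full(J, 0.004)
        seG = np.full(J, 0.008)
        G = 0.2 * g + rng.normal(0, seG * 0.8)
        G[J // 2] += shift * seG[J // 2]
        return harmonized_from_arrays(g, seg, G, seG, n_exp=30_000, n_out=30_000), f"rs{J // 2 + 1}"

    def test_planted_outlier_flagged_and_corrected(self):
        h, outlier = self._planted_outlier(3)
        res = mr_presso(h, n_sim=1000, seed=3)
        assert outlier in res.outlier_ids
        assert abs(res.beta_corrected.beta - 0.2) < abs(res.beta_raw.beta - 0.2)
        assert res.global_p < 0.05

    def test_proportional_data_global_p_large(self, rng):
        g = rng.uniform(0.05, 0.15, 10)
        seG = np.full(10, 0.01)
        G = 0.2 * g + rng.normal(0, seG * 0.5)
        h = harmonized_from_arrays(g, np.full(10, 0.004), G, seG,
                                   n_exp=30_000, n_out=30_000)
        res = mr_presso(h, n_sim=500, seed=1)
        assert res.global_p >= 0.5
        assert res.outlier_ids == []

    def test_determinism_same_seed(self):
        h, _ = self._planted_outlier(5)
        a = mr_presso(h, n_sim=1000, seed=11)
        b = mr_presso(h, n_sim=1000, seed=11)
        assert a.rss_obs == b.rss_obs
        assert a.global_p == b.global_p
        assert a.outlier_ids == b.outlier_ids
        assert a.outlier_p.equals(b.outlier_p)
        assert (a.distortion_p == b.distortion_p)
        assert a.beta_corrected.beta == b.beta_corrected.beta

    def test_too_few_snps(self):
        h = harmonized_from_arrays([0.1] * 3, [0.01] * 3, [0.02] * 3, [0.01] * 3,
                                   n_exp=1000, n_out=1000)
        with pytest.raises(EstimationError):
            mr_presso(h, seed=1)


class TestDirectionality:
    def test_forward_generated_data_valid(self):
        valid = 0
        for seed in range(30):
            cfg = SimulationConfig(J=30, beta_true=0.1)
            exp, out, _ = simulate_two_sample(cfg, seed=seed)
            h = harmonize(exp, out)
            valid += steiger_directionality(h).valid
        assert valid / 30 > 0.95

    def test_equal_totals_z_zero(self):
        h = harmonized_from_arrays([0.1], [0.01], [0.1], [0.01],
                                   n_exp=10_000, n_out=10_000)
        res = steiger_directionality(h)
        assert res.steiger_z == pytest.approx(0.0)
        assert res.steiger_p == pytest.approx(1.0)
        assert not res.valid  # tie is not evidence for the forward direction

    def test_swapping_roles_flips_verdict(self, rng):
        h = _random_instance(rng)
        g, seg, G, seG = h.arrays()
        fwd = steiger_directionality(h)
        h_rev = harmonized_from_arrays(G, seG, g, seg, n_exp=30_000, n_out=30_000)
        rev = steiger_directionality(h_rev)
        assert fwd.valid != rev.valid
        assert fwd.steiger_z == pytest.approx(-rev.steiger_z, rel=1e-10)


class TestLeaveOneOut:
    def test_structure(self, proportional_harmonized):
        res = leave_one_out(proportional_harmonized)
        assert len(res) == 5
        assert all(e.n_snps == 4 for _, e in res)

    def test_homogeneous_estimates_stay_inside_full_ci(self, small_harmonized):
        full = ivw(small_harmonized, random_effects=False)
        for _, e in leave_one_out(small_harmonized):
            assert full.ci_low <= e.beta <= full.ci_high

    def test_largest_shift_from_planted_outlier(self):
        rng = np.random.default_rng(8)
        g = rng.uniform(0.05, 0.15, 12)
        seG = np.full(12, 0.008)
        G = 0.2 * g + rng.normal(0, seG * 0.5)
        G[4] += 12 * seG[4]
        h = harmonized_from_arrays(g, np.full(12, 0.004), G, seG,
                                   n_exp=30_000, n_out=30_000)
        full = ivw(h).beta
        shifts = {s: abs(e.beta - full) for s, e in leave_one_out(h)}
        assert max(shifts, key=shifts.get) == "rs5"
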