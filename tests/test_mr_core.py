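"""MR estimators: Wald ratio, IVW, Egger, weighted median, sensitivity."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

from protmr import synthetic_data
from protmr.gwas_io import harmonize
from protmr.mr_core import (
    cochran_q,
    estimate,
    ivw,
    leave_one_out,
    mr_egger,
    select_primary_method,
    sensitivity_report,
    to_odds_ratio,
    wald_ratio,
    weighted_median,
)

from .conftest import make_pairs


def random_pairs(rng, k):
    return make_pairs(
        beta_exp=rng.normal(0.3, 0.2, k) + 0.05,
        beta_out=rng.normal(0.1, 0.1, k),
        se_out=rng.uniform(0.02, 0.2, k),
    )


class TestWaldRatio:
    def test_ratio_and_delta_se(self):
        est = wald_ratio(make_pairs([0.5], [0.1], se_out=[0.05]))
        assert est.theta == pytest.approx(0.2)
        assert est.se == pytest.approx(0.1)

    def test_negative_exposure_flips_sign(self):
        est = wald_ratio(make_pairs([-0.5], [0.1], se_out=[0.05]))
        assert est.theta == pytest.approx(-0.2)
        assert est.se == pytest.approx(0.1)

    def test_null_outcome(self):
        est = wald_ratio(make_pairs([0.5], [0.0], se_out=[0.05]))
        assert est.theta == 0.0
        assert est.pval == pytest.approx(1.0)

    def test_zero_exposure_beta_raises(self):
        with pytest.raises(ValueError, match="undefined ratio"):
            wald_ratio(make_pairs([0.0], [0.1]))


class TestIVW:
    def test_equal_weight_mean(self):
        est = ivw(make_pairs([1.0, 1.0], [0.2, 0.4], se_out=[1.0, 1.0]), "fixed")
        assert est.theta == pytest.approx(0.3)
        assert est.se == pytest.approx(1 / np.sqrt(2))

    def test_matches_wls_through_origin_oracle(self, rng):
        for _ in range(50):
            pairs = random_pairs(rng, int(rng.integers(2, 30)))
            est = ivw(pairs, "fixed")
            w = 1.0 / pairs["se_out"] ** 2
            fit = sm.WLS(pairs["beta_out"], pairs[["beta_exp"]], weights=w).fit()
            assert est.theta == pytest.approx(fit.params.iloc[0], abs=1e-10)
            # fixed-effect SE is the no-dispersion WLS SE
            se_oracle = float(np.sqrt(1.0 / np.sum(w * pairs["beta_exp"] ** 2)))
            assert est.se == pytest.approx(se_oracle, abs=1e-12)

    def test_homogeneous_ratios_floor_random_se_at_fixed(self):
        pairs = make_pairs([0.5, 0.4, 0.2, 0.3], [0.15, 0.12, 0.06, 0.09], se_out=[0.05] * 4)
        fixed = ivw(pairs, "fixed")
        random = ivw(pairs, "random")
        assert random.se == pytest.approx(fixed.se)

    def test_random_se_never_below_fixed(self, rng):
        for _ in range(20):
            pairs = random_pairs(rng, 8)
            assert ivw(pairs, "random").se >= ivw(pairs, "fixed").se

    def test_single_pair_matches_wald_via_wls_form(self):
        """The WLS-through-origin closed form at k=1 is the Wald ratio."""
        pairs = make_pairs([0.4], [0.12], se_out=[0.07])
        wald = wald_ratio(pairs)
        w = 1.0 / pairs["se_out"] ** 2
        theta = float(np.sum(w * pairs["beta_exp"] * pairs["beta_out"]) / np.sum(w * pairs["beta_exp"] ** 2))
        se = float(np.sqrt(1.0 / np.sum(w * pairs["beta_exp"] ** 2)))
        assert wald.theta == pytest.approx(theta, abs=1e-12)
        assert wald.se == pytest.approx(se, abs=1e-12)

    def test_k1_is_hard_error(self):
        with pytest.raises(ValueError, match="wald_ratio"):
            ivw(make_pairs([0.5], [0.1]))


class TestCochranQ:
    def test_identical_ratios_give_zero(self):
        pairs = make_pairs([0.5, 0.25], [0.1, 0.05], se_out=[0.05, 0.05])
        q, df, p = cochran_q(pairs, ivw(pairs, "fixed").theta)
        assert q == pytest.approx(0.0, abs=1e-20)
        assert df == 1
        assert p == pytest.approx(1.0)

    def test_hand_computed_value(self):
        # w=(1,1): ratios (0,1), reference 0.5 → Q = 0.25 + 0.25
        pairs = make_pairs([1.0, 1.0], [0.0, 1.0], se_out=[1.0, 1.0])
        q, df, _ = cochran_q(pairs, 0.5)
        assert q == pytest.approx(0.5)

    def test_null_pvalues_approximately_uniform(self, rng):
        n_rep, k = 400, 10
        ps = []
        for _ in range(n_rep):
            bx = rng.normal(0.5, 0.1, k)
            so = np.full(k, 0.05)
            bo = 0.2 * bx + rng.normal(0, so)
            pairs = make_pairs(bx, bo, se_out=so)
            _, _, p = cochran_q(pairs, ivw(pairs, "fixed").theta)
            ps.append(p)
        rej = np.mean(np.array(ps) < 0.05)
        # binomial 99.9% envelope around 0.05 for 400 draws
        assert abs(rej - 0.05) < 3.3 * np.sqrt(0.05 * 0.95 / n_rep)


class TestEgger:
    def test_exact_line_recovered(self):
        bx = np.array([0.2, 0.4, 0.6, 0.8])
        pairs = make_pairs(bx, 0.1 + 0.4 * bx, se_out=[0.05] * 4)
        res = mr_egger(pairs)
        assert res.slope.theta == pytest.approx(0.4, abs=1e-10)
        assert res.intercept == pytest.approx(0.1, abs=1e-10)

    def test_matches_wls_with_intercept_oracle(self, rng):
        for _ in range(50):
            k = int(rng.integers(3, 30))
            pairs = random_pairs(rng, k)
            res = mr_egger(pairs)
            sign = np.where(pairs["beta_exp"] < 0, -1.0, 1.0)
            x = sm.add_constant(pairs["beta_exp"] * sign)
            y = pairs["beta_out"] * sign
            fit = sm.WLS(y, x, weights=1.0 / pairs["se_out"] ** 2).fit()
            assert res.slope.theta == pytest.approx(fit.params.iloc[1], abs=1e-10)
            assert res.intercept == pytest.approx(fit.params.iloc[0], abs=1e-10)

    def test_orientation_invariance(self, rng):
        pairs = random_pairs(rng, 10)
        flipped = pairs.copy()
        flip = rng.random(10) < 0.5
        flipped.loc[flip, "beta_exp"] *= -1
        flipped.loc[flip, "beta_out"] *= -1
        a, b = mr_egger(pairs), mr_egger(flipped)
        assert a.slope.theta == pytest.approx(b.slope.theta)
        assert a.intercept == pytest.approx(b.intercept)

    def test_requires_three_instruments(self):
        with pytest.raises(ValueError, match="≥3"):
            mr_egger(make_pairs([0.5, 0.4], [0.1, 0.1]))


class TestWeightedMedian:
    def test_equal_weights_return_middle_ratio(self):
        pairs = make_pairs([1.0, 1.0, 1.0], [0.1, 0.3, 0.9], se_out=[0.1] * 3)
        est = weighted_median(pairs, n_boot=100, seed=1)
        assert est.theta == pytest.approx(0.3)

    def test_dominant_instrument_pins_the_median(self):
        # first IV carries ~96% of the weight
        pairs = make_pairs([1.0, 1.0, 1.0], [0.5, 0.1, 0.9], se_out=[0.01, 0.05, 0.05])
        est = weighted_median(pairs, n_boot=100, seed=1)
        assert est.theta == pytest.approx(0.5, abs=0.05)

    def test_same_seed_reproduces_bootstrap_se(self, rng):
        pairs = random_pairs(rng, 7)
        a = weighted_median(pairs, n_boot=500, seed=42)
        b = weighted_median(pairs, n_boot=500, seed=42)
        assert a.se == b.se

    def test_seed_is_mandatory(self):
        with pytest.raises(ValueError, match="seed"):
            weighted_median(make_pairs([1, 1, 1], [0.1, 0.2, 0.3]))

    def test_robust_to_minority_invalid_instruments(self, rng):
        """With 40% strongly pleiotropic IVs the median beats IVW on bias."""
        theta = 0.3
        biases_wm, biases_ivw = [], []
        for _ in range(60):
            k = 15
            bx = rng.uniform(0.2, 0.6, k)
            so = np.full(k, 0.03)
            alpha = np.zeros(k)
            alpha[:6] = 0.15  # 6/15 invalid, large directional pleiotropy
            bo = theta * bx + alpha + rng.normal(0, so)
            pairs = make_pairs(bx, bo, se_out=so)
            biases_wm.append(weighted_median(pairs, n_boot=50, seed=3).theta - theta)
            biases_ivw.append(ivw(pairs, "fixed").theta - theta)
        assert abs(np.mean(biases_wm)) < abs(np.mean(biases_ivw))


class TestMethodSelection:
    @pytest.mark.parametrize(
        "k,method",
        [(1, "wald_ratio"), (2, "ivw_fixed"), (3, "ivw_fixed"), (4, "ivw_random"), (7, "ivw_random")],
    )
    def test_count_rule(self, k, method):
        assert select_primary_method(k) == method

    def test_nonpositive_count_raises(self):
        with pytest.raises(ValueError):
            select_primary_method(0)


class TestOddsRatio:
    def test_known_interval(self):
        or_, lo, hi = to_odds_ratio(0.0, 0.1)
        assert or_ == pytest.approx(1.0)
        assert lo == pytest.approx(np.exp(-0.196), abs=1e-12)
        assert hi == pytest.approx(np.exp(0.196), abs=1e-12)

    def test_degenerate_se(self):
        assert to_odds_ratio(0.0, 0.0) == (1.0, 1.0, 1.0)

    def test_estimate_ci_consistency(self, rng):
        pairs = random_pairs(rng, 6)
        est = ivw(pairs, "random")
        assert est.ci_low == pytest.approx(est.theta - 1.96 * est.se, abs=1e-9)
        assert est.ci_high == pytest.approx(est.theta + 1.96 * est.se, abs=1e-9)
        assert est.or_ == pytest.approx(np.exp(est.theta))
        assert est.or_low == pytest.approx(np.exp(est.ci_low))


class TestLeaveOneOut:
    def test_three_instruments_give_three_fixed_ivw_fits(self, rng):
        pairs = random_pairs(rng, 3)
        loo = leave_one_out(pairs)
        assert len(loo) == 3
        assert all(est.method == "ivw_fixed" for _, est in loo)
        assert [vid for vid, _ in loo] == list(pairs["variant_id"])

    def test_removing_on_estimate_ratio_leaves_estimate_unchanged(self):
        # all ratios identical → removing any one cannot move the estimate
        pairs = make_pairs([0.5, 0.4, 0.2], [0.15, 0.12, 0.06], se_out=[0.05] * 3)
        full = ivw(pairs, "fixed").theta
        for _, est in leave_one_out(pairs):
            assert est.theta == pytest.approx(full, abs=1e-12)

    def test_strong_signal_keeps_sign(self, rng):
        cfg = synthetic_data.SimulationConfig(n_variants=10, theta_true=0.5, seed=11)
        exp, out, _ = synthetic_data.simulate_instrument_panel(cfg)
        pairs = harmonize(exp, out)
        full = estimate(pairs)
        for _, est in leave_one_out(pairs):
            assert np.sign(est.theta) == np.sign(full.theta)


class TestSignFlipEquivariance:
    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 2**20))
    def test_all_estimators_invariant_under_joint_flip(self, seed):
        rng = np.random.default_rng(seed)
        k = 8
        pairs = random_pairs(rng, k)
        flipped = pairs.copy()
        flip = rng.random(k) < 0.5
        flipped.loc[flip, "beta_exp"] *= -1
        flipped.loc[flip, "beta_out"] *= -1
        assert ivw(pairs, "fixed").theta == pytest.approx(ivw(flipped, "fixed").theta)
        assert ivw(pairs, "random").se == pytest.approx(ivw(flipped, "random").se)
        assert mr_egger(pairs).slope.theta == pytest.approx(mr_egger(flipped).slope.theta)
        wm_a = weighted_median(pairs, n_boot=50, seed=1).theta
        wm_b = weighted_median(flipped, n_boot=50, seed=1).theta
        assert wm_a == pytest.approx(wm_b)


class TestSensitivityReport:
    def test_report_fields_consistent(self, rng):
        pairs = random_pairs(rng, 6)
        rep = sensitivity_report(pairs)
        assert rep.q_df == 5
        assert rep.q_stat >= 0
        assert len(rep.loo) == 6
        assert rep.pleiotropy_flag == (rep.egger_intercept_pval < 0.05)
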