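"""MR estimators: Wald ratio, IVW, GLS-IVW, rescaling and orientation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from helpers import wls_origin_oracle

from dtmr import mr
from dtmr.sumstats import LDMatrix


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    est=st.floats(-3, 3),
    se=st.floats(0.01, 2),
    a=st.floats(0.1, 5),
    b=st.floats(0.1, 5),
)
def test_rescaling_composes_and_orientation_is_involutive(est, se, a, b):
    base = mr._finish(est, se, n_snps=2, method="ivw_fixed")
    once = mr.rescale_log_or(base, a * b)
    twice = mr.rescale_log_or(mr.rescale_log_or(base, a), b)
    assert once.estimate == pytest.approx(twice.estimate, rel=1e-12, abs=1e-12)
    assert once.se == pytest.approx(twice.se, rel=1e-12, abs=1e-12)
    flipped = mr.orient_to_lowering(mr.orient_to_lowering(base))
    assert flipped.estimate == base.estimate
    assert flipped.ci_low == base.ci_low


class TestWaldRatio:
    def test_ratio_arithmetic(self):
        res = mr.wald_ratio(bx=-0.5, sx=0.02, by=-0.2, sy=0.05)
        assert res.estimate == pytest.approx(0.4)
        assert res.se == pytest.approx(0.1)
        assert res.n_snps == 1

    def test_splice_donor_tg_per_sd_protein(self):
        # per-allele effects of the APOC3 splice-donor PTV: -2.19 s.d. protein,
        # -0.86 mmol/L TG -> TG change per s.d. protein is their ratio
        res = mr.wald_ratio(bx=-2.19, sx=0.05, by=-0.86, sy=0.02)
        assert res.estimate == pytest.approx(0.3927, abs=5e-5)

    def test_null_outcome_gives_p_one(self):
        res = mr.wald_ratio(bx=-0.5, sx=0.02, by=0.0, sy=0.05)
        assert res.estimate == 0.0
        assert res.pvalue == pytest.approx(1.0)

    def test_zero_exposure_beta_is_error(self):
        with pytest.raises(ValueError, match="weak"):
            mr.wald_ratio(bx=0.0, sx=0.02, by=0.1, sy=0.05)


class TestIVW:
    def test_single_instrument_equals_wald(self):
        a = mr.ivw(([0.4], [0.01], [-0.2], [0.05]))
        b = mr.wald_ratio(0.4, 0.01, -0.2, 0.05)
        assert a.estimate == pytest.approx(b.estimate, abs=1e-12)
        assert a.se == pytest.approx(b.se, abs=1e-12)

    def test_identical_ratios_give_zero_q(self):
        res = mr.ivw(([0.5, 0.5], [0.01, 0.01], [0.25, 0.25], [0.05, 0.05]))
        assert res.estimate == pytest.approx(0.5)
        assert res.q_stat == pytest.approx(0.0, abs=1e-12)

    def test_matches_weighted_regression_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            k = int(rng.integers(2, 12))
            bx = rng.normal(0.3, 0.1, k)
            sy = rng.uniform(0.01, 0.2, k)
            by = -0.5 * bx + rng.normal(0, sy)
            res = mr.ivw((bx, np.full(k, 0.01), by, sy))
            assert res.estimate == pytest.approx(wls_origin_oracle(bx, by, sy), abs=1e-10)

    def test_random_effects_never_shrinks_se(self):
        rng = np.random.default_rng(9)
        bx = rng.normal(0.3, 0.1, 8)
        sy = rng.uniform(0.01, 0.05, 8)
        by = -0.5 * bx + rng.normal(0, 5 * sy)  # overdispersed
        fixed = mr.ivw((bx, None, by, sy), "fixed")
        random = mr.ivw((bx, None, by, sy), "random")
        assert random.se >= fixed.se
        assert random.estimate == pytest.approx(fixed.estimate)

    def test_random_effects_single_instrument_falls_back(self):
        with pytest.warns(UserWarning, match="falling back"):
            res = mr.ivw(([0.4], [0.01], [-0.2], [0.05]), "random")
        assert res.method == "ivw_fixed"

    def test_recovers_simulated_effect(self):
        rng = np.random.default_rng(17)
        k, theta = 10, -0.5
        bx = rng.normal(0.3, 0.05, k)
        sy = np.full(k, 0.02)
        by = theta * bx + rng.normal(0, sy)
        res = mr.ivw((bx, np.full(k, 0.005), by, sy))
        assert abs(res.estimate - theta) < 3 * res.se


class TestGlsIvw:
    def test_identity_ld_reduces_to_fixed_ivw(self):
        rng = np.random.default_rng(21)
        k = 6
        bx = rng.normal(0.3, 0.05, k)
        sy = rng.uniform(0.01, 0.05, k)
        by = -0.5 * bx + rng.normal(0, sy)
        gls = mr.gls_ivw((bx, None, by, sy), np.eye(k))
        ivw = mr.ivw((bx, None, by, sy))
        assert gls.estimate == pytest.approx(ivw.estimate, abs=1e-10)
        assert gls.se == pytest.approx(ivw.se, abs=1e-10)

    def test_near_duplicate_instruments_do_not_double_information(self):
        # closed form: for a duplicated instrument pair at correlation r the
        # GLS variance is s^2 (1 + r) / (2 bx^2) -> the single-instrument
        # variance as r -> 1
        bx, sy, r = 0.4, 0.05, 0.999
        ld = np.array([[1.0, r], [r, 1.0]])
        pair = mr.gls_ivw(([bx, bx], None, [-0.2, -0.2], [sy, sy]), ld)
        single = mr.wald_ratio(bx, 0.0, -0.2, sy)
        expected_se = math.sqrt(sy**2 * (1 + r) / (2 * bx**2))
        assert pair.se == pytest.approx(expected_se, rel=1e-10)
        assert pair.se == pytest.approx(single.se, rel=1e-3)

    def test_ill_conditioned_covariance_raises(self):
        r = 1.0 - 1e-12
        ld = np.array([[1.0, r], [r, 1.0]])
        with pytest.raises(ValueError, match="clump"):
            mr.gls_ivw(([0.4, 0.4], None, [-0.2, -0.2], [0.05, 0.05]), ld)

    def test_chain_of_reductions_at_k1(self):
        gls = mr.gls_ivw(([0.4], None, [-0.2], [0.05]), np.eye(1))
        ivw = mr.ivw(([0.4], None, [-0.2], [0.05]))
        wald = mr.wald_ratio(0.4, 0.0, -0.2, 0.05)
        for a, b in [(gls, ivw), (ivw, wald)]:
            assert a.estimate == pytest.approx(b.estimate, abs=1e-10)
            assert a.se == pytest.approx(b.se, abs=1e-10)
            assert a.pvalue == pytest.approx(b.pvalue, abs=1e-10)

    def test_accepts_ldmatrix_object(self):
        ld = LDMatrix(["a", "b"], np.array([[1.0, 0.3], [0.3, 1.0]]))
        res = mr.gls_ivw(([0.4, 0.3], None, [-0.2, -0.15], [0.05, 0.05]), ld)
        assert res.n_snps == 2
        assert res.condition_number is not None


class TestRescaleAndOrient:
    def test_reproduces_translated_cad_odds_ratio(self):
        # OR 0.43 per mmol/L TG, achieved lowering 0.58 mmol/L -> OR 0.61
        base = mr._finish(math.log(0.43), 0.089, n_snps=3, method="gls_ivw")
        scaled = mr.rescale_log_or(base, 0.58)
        assert round(scaled.odds_ratio, 2) == 0.61

    def test_factor_one_is_identity(self):
        base = mr._finish(-0.5, 0.1, n_snps=2, method="ivw_fixed")
        scaled = mr.rescale_log_or(base, 1.0)
        assert scaled.estimate == base.estimate
        assert scaled.ci_low == base.ci_low

    def test_log_linear_scaling(self):
        base = mr._finish(math.log(0.5), 0.1, n_snps=1, method="wald_ratio")
        assert mr.rescale_log_or(base, 2.0).odds_ratio == pytest.approx(0.25)

    def test_rescaling_composes(self):
        base = mr._finish(-0.8, 0.2, n_snps=4, method="gls_ivw")
        once = mr.rescale_log_or(base, 0.3 * 1.7)
        twice = mr.rescale_log_or(mr.rescale_log_or(base, 0.3), 1.7)
        assert once.estimate == pytest.approx(twice.estimate, abs=1e-12)
        assert once.se == pytest.approx(twice.se, abs=1e-12)

    def test_orientation_flip_negates_and_swaps_ci(self):
        base = mr._finish(0.3, 0.102, n_snps=1, method="wald_ratio")
        flipped = mr.orient_to_lowering(base)
        assert flipped.estimate == pytest.approx(-0.3)
        assert flipped.ci_low == pytest.approx(-base.ci_high)
        assert flipped.ci_high == pytest.approx(-base.ci_low)

    def test_double_flip_is_identity_and_null_fixed_point(self):
        base = mr._finish(0.3, 0.1, n_snps=1, method="wald_ratio")
        double = mr.orient_to_lowering(mr.orient_to_lowering(base))
        assert double.estimate == base.estimate
        null = mr._finish(0.0, 0.1, n_snps=1, method="wald_ratio")
        assert mr.orient_to_lowering(null).estimate == 0.0

    def test_multiplicity_widens_ci(self):
        narrow = mr.wald_ratio(0.4, 0.0, -0.2, 0.05, m=1)
        wide = mr.wald_ratio(0.4, 0.0, -0.2, 0.05, m=40)
        assert wide.ci_high - wide.ci_low > narrow.ci_high - narrow.ci_low
        # CI at level 1 - 0.05/m
        from scipy import stats

        crit = stats.norm.ppf(1 - 0.05 / (2 * 40))
        assert wide.ci_high == pytest.approx(wide.estimate + crit * wide.se)
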