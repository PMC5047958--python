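import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import qifcal as q
from qifcal import synthetic as syn


def records(case_ids, scores, platform="P"):
    return pd.DataFrame(
        {"case_id": case_ids, "platform_id": platform, "score": scores}
    )


class TestLogTransform:
    def test_natural_log(self):
        rec = q.log_transform(records(["a", "b"], [1.0, np.e**2]))
        assert np.allclose(rec["log_score"], [0.0, 2.0])

    def test_nonpositive_score_names_case(self):
        with pytest.raises(ValueError, match="bad_case"):
            q.log_transform(records(["ok", "bad_case"], [1.0, 0.0]))


class TestPairCases:
    def test_inner_join_drops_unmatched(self):
        x = q.log_transform(records([1, 2, 3], [1.0, 2.0, 3.0]))
        y = q.log_transform(records([2, 3, 4], [1.0, 2.0, 3.0]))
        pairs = q.pair_cases(x, y)
        assert sorted(pairs["case_id"]) == [2, 3]

    def test_identical_case_sets_no_drops(self):
        x = q.log_transform(records([1, 2, 3], [1.0, 2.0, 3.0]))
        assert len(q.pair_cases(x, x)) == 3

    def test_duplicate_case_id_is_ambiguous(self):
        x = q.log_transform(records([1, 1, 2], [1.0, 2.0, 3.0]))
        y = q.log_transform(records([1, 2, 3], [1.0, 2.0, 3.0]))
        with pytest.raises(ValueError, match="duplicate"):
            q.pair_cases(x, y)

    def test_zero_overlap_rejected(self):
        x = q.log_transform(records([1, 2], [1.0, 2.0]))
        y = q.log_transform(records([3, 4], [1.0, 2.0]))
        with pytest.raises(ValueError, match="overlap"):
            q.pair_cases(x, y)


class TestBaRegression:
    def test_identical_assays(self):
        x = np.linspace(0, 3, 20)
        fit = q.ba_regression(x, x)
        assert fit.intercept_a == pytest.approx(0.0, abs=1e-12)
        assert fit.slope_b == pytest.approx(0.0, abs=1e-12)
        assert fit.resid_sd == pytest.approx(0.0, abs=1e-10)

    def test_noise_free_affine_relation(self):
        # y = 0.43 + 0.95 x implies D = 0.441026 - 0.051282 A
        x = np.linspace(0.5, 4.0, 37)
        fit = q.ba_regression(x, 0.43 + 0.95 * x)
        assert fit.intercept_a == pytest.approx(0.441026, abs=1e-5)
        assert fit.slope_b == pytest.approx(-0.051282, abs=1e-5)
        assert fit.resid_sd < 1e-10

    def test_pure_offset(self):
        x = np.linspace(0, 3, 10)
        fit = q.ba_regression(x, x + 0.5)
        assert fit.intercept_a == pytest.approx(0.5)
        assert fit.slope_b == pytest.approx(0.0, abs=1e-12)

    def test_constant_averages_rejected(self):
        x = np.array([1.0, 1.0, 1.0])
        with pytest.raises(ValueError):
            q.ba_regression(x, x)


class TestConversion:
    def test_identity_fit_gives_identity_model(self):
        m = q.conversion_from_ba(q.DifferenceMeanFit(0.0, 0.0, 0.0, 10))
        assert (m.alpha, m.beta) == (0.0, 1.0)

    def test_recovers_printed_equation(self):
        m = q.conversion_from_ba(q.DifferenceMeanFit(0.441026, -0.051282, 0.0, 10))
        assert m.alpha == pytest.approx(0.43, abs=1e-5)
        assert m.beta == pytest.approx(0.95, abs=1e-5)

    def test_zero_slope_is_mean_offset(self):
        m = q.conversion_from_ba(q.DifferenceMeanFit(0.5, 0.0, 0.0, 10))
        assert (m.alpha, m.beta) == (0.5, 1.0)

    def test_degenerate_slope_rejected(self):
        with pytest.raises(ValueError):
            q.conversion_from_ba(q.DifferenceMeanFit(0.1, 2.0, 0.0, 10))

    def test_exact_recovery_from_noise_free_platforms(self, noisefree_platforms):
        """Calibration recovers the generating platform ratio exactly."""
        pa, pb = noisefree_platforms
        coh = syn.simulate_latent(60, seed=1)
        a = syn.apply_platform(coh, pa, seed=1)
        b = syn.apply_platform(coh, pb, seed=1)
        fit = q.ba_regression(a["log_score"].to_numpy(), b["log_score"].to_numpy())
        m = q.conversion_from_ba(fit, pa.platform_id, pb.platform_id)
        beta_true = pb.beta / pa.beta
        alpha_true = pb.alpha - beta_true * pa.alpha
        assert m.beta == pytest.approx(beta_true, abs=1e-9)
        assert m.alpha == pytest.approx(alpha_true, abs=1e-9)
        assert fit.resid_sd == pytest.approx(0.0, abs=1e-9)

    def test_parameter_recovery_under_noise(self):
        """n=323 pairs, true (0.43, 0.95), per-platform noise sd 0.05."""
        ok = 0
        reps = 30
        for s in range(reps):
            coh = syn.simulate_latent(323, seed=s)
            a = syn.apply_platform(coh, syn.PlatformSpec("A", 0, 1, 0.05), seed=s)
            b = syn.apply_platform(coh, syn.PlatformSpec("B", 0.43, 0.95, 0.05), seed=s)
            fit = q.ba_regression(a["log_score"].to_numpy(), b["log_score"].to_numpy())
            m = q.conversion_from_ba(fit, "A", "B")
            ok += abs(m.alpha - 0.43) <= 0.05 and abs(m.beta - 0.95) <= 0.03
        assert ok / reps >= 0.95


class TestInvertApply:
    def test_identity_is_self_inverse(self):
        m = q.CalibrationModel("A", "B", 0.0, 1.0)
        inv = q.invert_calibration(m)
        assert (inv.alpha, inv.beta) == (0.0, 1.0)
        assert (inv.from_platform, inv.to_platform) == ("B", "A")

    def test_inverse_of_printed_forward_equation(self):
        inv = q.invert_calibration(q.CalibrationModel("A", "B", 0.43, 0.95))
        assert inv.alpha == pytest.approx(-0.45263, abs=1e-4)
        assert inv.beta == pytest.approx(1.05263, abs=1e-4)

    @given(
        alpha=st.floats(-2, 2), beta=st.floats(0.2, 5.0),
        v=st.floats(-5, 5),
    )
    @settings(max_examples=50, deadline=None)
    def test_involution_and_round_trip(self, alpha, beta, v):
        m = q.CalibrationModel("A", "B", alpha, beta)
        mm = q.invert_calibration(q.invert_calibration(m))
        assert mm.alpha == pytest.approx(m.alpha, abs=1e-9)
        assert mm.beta == pytest.approx(m.beta, rel=1e-12)
        out = q.apply_calibration(
            q.invert_calibration(m), q.apply_calibration(m, np.array([v]))
        )
        assert out[0] == pytest.approx(v, abs=1e-9)

    def test_apply_printed_coefficients(self):
        m = q.CalibrationModel("A", "B", 0.43, 0.95)
        assert q.apply_calibration(m, np.array([2.0]))[0] == pytest.approx(2.33)

    def test_symmetry_with_swapped_regression(self):
        """Noise-free: converting the swapped fit equals the inverse model."""
        x = np.linspace(0.5, 4.0, 25)
        y = 0.43 + 0.95 * x
        fwd = q.conversion_from_ba(q.ba_regression(x, y), "A", "B")
        rev = q.conversion_from_ba(q.ba_regression(y, x), "B", "A")
        inv = q.invert_calibration(fwd)
        assert rev.alpha == pytest.approx(inv.alpha, abs=1e-9)
        assert rev.beta == pytest.approx(inv.beta, abs=1e-9)


class TestLimitsOfAgreement:
    def test_zero_residual_lines_coincide(self):
        fit = q.DifferenceMeanFit(0.1, 0.02, 0.0, 10)
        lo, hi = q.limits_of_agreement(fit)
        assert lo == hi == (0.1, 0.02)

    @pytest.mark.parametrize(
        "level,halfwidth", [(0.95, 1.959964), (0.5, 0.674490)]
    )
    def test_normal_quantile_halfwidths(self, level, halfwidth):
        fit = q.DifferenceMeanFit(0.0, 0.0, 1.0, 10)
        lo, hi = q.limits_of_agreement(fit, level=level)
        assert hi[0] == pytest.approx(halfwidth, abs=1e-5)
        assert lo[0] == pytest.approx(-halfwidth, abs=1e-5)

    def test_invalid_level_rejected(self):
        with pytest.raises(ValueError):
            q.limits_of_agreement(q.DifferenceMeanFit(0, 0, 1, 10), level=1.0)
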