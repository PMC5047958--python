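import numpy as np
import pandas as pd
import pytest
from lifelines.statistics import multivariate_logrank_test

import qifcal as q
from qifcal import synthetic as syn
from qifcal.cutpoints import logrank_scan


class TestPercentileCutpoint:
    def test_fifteenth_percentile_of_twenty(self):
        assert q.percentile_cutpoint(np.arange(1, 21), 15) == 3.0
        assert np.mean(np.arange(1, 21) <= 3.0) == 0.15

    def test_upper_boundary(self):
        vals = np.arange(1, 11)
        thr = q.percentile_cutpoint(vals, 99.9)
        assert thr == vals.max()

    def test_all_equal_degenerate(self):
        vals = np.full(6, 2.5)
        thr = q.percentile_cutpoint(vals, 15)
        assert thr == 2.5
        assert np.mean(vals <= thr) == 1.0  # caller must treat as degenerate

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            q.percentile_cutpoint(np.array([]), 15)


class TestTransferDichotomize:
    def test_identity_transfer(self):
        m = q.CalibrationModel("A", "B", 0.0, 1.0)
        assert q.transfer_cutpoint(1.7, m) == 1.7

    def test_printed_coefficients(self):
        m = q.CalibrationModel("A", "B", 0.43, 0.95)
        assert q.transfer_cutpoint(2.0, m) == pytest.approx(2.33)

    def test_platform_mismatch_rejected(self):
        m = q.CalibrationModel("A", "B", 0.43, 0.95)
        with pytest.raises(ValueError, match="platform"):
            q.transfer_cutpoint(2.0, m, platform="B")

    def test_round_trip_restores_threshold(self):
        m = q.CalibrationModel("A", "B", 0.43, 0.95)
        back = q.transfer_cutpoint(q.transfer_cutpoint(2.0, m), q.invert_calibration(m))
        assert back == pytest.approx(2.0, abs=1e-12)

    def test_dichotomize_boundaries(self):
        vals = np.array([1.0, 2.0, 3.0])
        assert list(q.dichotomize(vals, 0.5)) == ["high"] * 3
        assert list(q.dichotomize(vals, 3.0)) == ["low"] * 3

    def test_frac_low_monotone_in_threshold(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=50)
        fracs = [np.mean(q.dichotomize(vals, t) == "low")
                 for t in np.linspace(-2, 2, 15)]
        assert np.all(np.diff(fracs) >= 0)


class TestLogrankScan:
    def test_matches_exhaustive_per_split_oracle(self):
        """Every candidate's chi-square equals a direct log-rank test."""
        rng = np.random.default_rng(4)
        n = 25
        t = rng.exponential(30, n)
        e = rng.integers(0, 2, n)
        e[:3] = 1
        marker = rng.normal(size=n)
        vals = np.sort(np.unique(marker))
        mids = (vals[:-1] + vals[1:]) / 2
        chi2 = logrank_scan(t, e, marker, mids)
        for c, x2 in zip(mids, chi2):
            lab = np.where(marker <= c, "low", "high")
            ref = multivariate_logrank_test(t, lab, e).test_statistic
            assert x2 == pytest.approx(ref, abs=1e-8)

    def test_invariant_under_monotone_marker_rescaling(self):
        rng = np.random.default_rng(6)
        t = rng.exponential(30, 60)
        e = rng.integers(0, 2, 60)
        e[:5] = 1
        marker = rng.normal(2, 0.5, 60)
        r1 = q.datadriven_cutpoint(marker, t, e, folds=3, seed=1)
        r2 = q.datadriven_cutpoint(np.exp(marker), t, e, folds=3, seed=1)
        # same split: identical low-group and statistic
        assert r1.frac_low == r2.frac_low
        assert r1.split_statistic == pytest.approx(r2.split_statistic, abs=1e-9)


class TestDatadrivenCutpoint:
    def test_recovers_generating_low_fraction(self):
        """True 20th-percentile split at HR 3.7 is recovered within 0.05."""
        coh = syn.simulate_latent(800, seed=50)
        meas = syn.apply_platform(coh, syn.PlatformSpec("A", 0, 1, 0.05), seed=50)
        clin = syn.simulate_survival(coh, syn.OutcomeSpec(), seed=50)
        res = q.datadriven_cutpoint(
            meas["log_score"].to_numpy(), clin["time_months"], clin["event"],
            folds=10, min_frac=0.10, seed=0,
        )
        assert abs(res.frac_low - 0.20) <= 0.05
        assert res.cv_supported

    def test_null_marker_rarely_cv_supported(self):
        """With hr_low=1 there is no real split for CV to confirm."""
        unsupported = 0
        reps = 20
        for s in range(reps):
            coh = syn.simulate_latent(300, seed=s)
            meas = syn.apply_platform(coh, syn.PlatformSpec("A", 0, 1, 0.05), seed=s)
            clin = syn.simulate_survival(coh, syn.OutcomeSpec(hr_low=1.0), seed=s)
            res = q.datadriven_cutpoint(
                meas["log_score"].to_numpy(), clin["time_months"], clin["event"],
                folds=10, min_frac=0.10, seed=s,
            )
            unsupported += not res.cv_supported
        assert unsupported / reps >= 0.75

    def test_constant_marker_rejected(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.array([1, 1, 1, 1])
        with pytest.raises(ValueError, match="candidate"):
            q.datadriven_cutpoint(np.full(4, 1.0), t, e, folds=2)

    def test_all_censored_rejected(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        with pytest.raises(ValueError, match="censored"):
            q.datadriven_cutpoint(np.arange(4.0), t, np.zeros(4, int), folds=2)

    def test_min_frac_respected(self):
        rng = np.random.default_rng(9)
        marker = rng.normal(size=100)
        t = rng.exponential(30, 100)
        e = np.ones(100, int)
        res = q.datadriven_cutpoint(marker, t, e, folds=2, min_frac=0.25, seed=0)
        assert 0.25 <= res.frac_low <= 0.75


class TestCrossPlatformAgreement:
    def test_transferred_classification_agreement_in_noise_regime(self, study):
        """Cutpoint transfer reproduces >= 95% classification agreement."""
        meas = study.measurements
        a = meas[meas["platform_id"] == "AQUA"]
        b = meas[meas["platform_id"] == "TissueStudio"]
        pairs = q.pair_cases(a, b)
        data = pairs.merge(study.clinical, on="case_id")
        model = q.conversion_from_ba(
            q.ba_regression(pairs["x"].to_numpy(), pairs["y"].to_numpy()),
            "AQUA", "TissueStudio",
        )
        cut = q.datadriven_cutpoint(
            data["x"].to_numpy(), data["time_months"], data["event"], seed=7
        )
        thr_b = q.transfer_cutpoint(cut.threshold, model, platform="AQUA")
        native = q.dichotomize(data["x"].to_numpy(), cut.threshold)
        transferred = q.dichotomize(data["y"].to_numpy(), thr_b)
        table = q.cross_tabulate(native, transferred)
        assert q.percent_agreement(table).percent >= 95.0

    def test_agreement_approaches_one_as_noise_vanishes(self, noisefree_platforms):
        pa, pb = noisefree_platforms
        coh = syn.simulate_latent(200, seed=2)
        a = syn.apply_platform(coh, pa, seed=2)
        b = syn.apply_platform(coh, pb, seed=2)
        pairs = q.pair_cases(a, b)
        model = q.conversion_from_ba(
            q.ba_regression(pairs["x"].to_numpy(), pairs["y"].to_numpy()), "A", "B"
        )
        thr = q.percentile_cutpoint(pairs["x"].to_numpy(), 20)
        native = q.dichotomize(pairs["x"].to_numpy(), thr)
        transferred = q.dichotomize(
            pairs["y"].to_numpy(), q.transfer_cutpoint(thr, model, platform="A")
        )
        assert q.percent_agreement(q.cross_tabulate(native, transferred)).percent == 100.0
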