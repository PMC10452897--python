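"""Baseline-hazard calibration and the competing-mortality risk integral."""

import numpy as np
import pytest
from scipy.stats import norm

from bcprs.io import RateTable
from bcprs.risk import (AbsoluteRiskModel, absolute_risk,
                        absolute_risk_with_survival, calibrate_baseline,
                        expected_case_counts, observed_case_counts,
                        risk_profiles)
from bcprs.simulate import (SimulationConfig, _sample_piecewise_times,
                            simulate_onset_cohort, synthetic_rates)

B = float(np.log(1.494))


class TestCalibration:
    def test_zero_effect_gives_identity(self, norwegian_like_rates):
        inc, _ = norwegian_like_rates
        hz = calibrate_baseline(inc, 0.0)
        _, lm = inc.yearly()
        np.testing.assert_allclose(hz.lambda0, lm, rtol=1e-12)

    def test_no_depletion_limit_is_lognormal_mean(self, norwegian_like_rates):
        """With negligible cumulative incidence the correction tends to
        1 / E[e^{bZ}] = e^{-b^2/2}."""
        inc, _ = norwegian_like_rates
        b = float(np.log(1.5))
        tiny = RateTable("incidence", inc.age_lo, inc.age_hi, inc.rate * 1e-4)
        hz = calibrate_baseline(tiny, b)
        _, lm = tiny.yearly()
        mask = lm > 0
        ratio = hz.lambda0[mask] / (lm[mask] * np.exp(-b ** 2 / 2))
        assert np.abs(ratio - 1).max() < 1e-3

    def test_naive_flag_matches_closed_form(self, norwegian_like_rates):
        inc, _ = norwegian_like_rates
        hz = calibrate_baseline(inc, B, depletion=False, n_quadrature=200_001)
        _, lm = inc.yearly()
        np.testing.assert_allclose(hz.lambda0, lm * np.exp(-B ** 2 / 2),
                                   rtol=1e-4)

    def test_depletion_raises_late_age_baseline(self, norwegian_like_rates):
        inc, _ = norwegian_like_rates
        dep = calibrate_baseline(inc, B)
        naive = calibrate_baseline(inc, B, depletion=False)
        assert dep.lambda0[-1] > naive.lambda0[-1]

    def test_simulated_incidence_reproduces_marginal(self, norwegian_like_rates):
        """Drawing a large population from the calibrated model recovers
        the marginal incidence in every fully covered decade."""
        inc, _ = norwegian_like_rates
        hz = calibrate_baseline(inc, B)
        rng = np.random.default_rng(1)
        n = 400_000
        z = rng.standard_normal(n)
        tab = RateTable("incidence", hz.ages, hz.ages + 1, hz.lambda0)
        onset = _sample_piecewise_times(tab, np.exp(B * z), rng)
        ages, lm = inc.yearly()
        for dec in range(30, 80, 10):
            events = ((onset >= dec) & (onset < dec + 10)).sum()
            py = sum((onset >= a).sum() for a in range(dec, dec + 10))
            obs = events / py
            exp = lm[(ages >= dec) & (ages < dec + 10)].mean()
            se = np.sqrt(events) / py
            assert obs == pytest.approx(exp, abs=4 * se + 1e-5 * exp)

    def test_infinite_b_rejected(self, norwegian_like_rates):
        inc, _ = norwegian_like_rates
        with pytest.raises(ValueError):
            calibrate_baseline(inc, np.inf)


class TestAbsoluteRisk:
    def test_constant_hazard_no_mortality(self, constant_incidence):
        hz = calibrate_baseline(constant_incidence, 0.0)
        r = absolute_risk(20, 10, 0.0, hz, None)
        assert r == pytest.approx(1 - np.exp(-0.1), abs=1e-12)

    def test_cause_specific_share_long_horizon(self, constant_incidence,
                                               constant_mortality):
        hz = calibrate_baseline(constant_incidence, 0.0)
        r = absolute_risk(0, 100, 0.0, hz, constant_mortality)
        # tau -> inf limit is lambda / (lambda + m) = 0.5
        assert r == pytest.approx(0.5 * (1 - np.exp(-2.0)), abs=1e-12)

    def test_constant_hazards_closed_form(self, constant_incidence,
                                          constant_mortality):
        hz = calibrate_baseline(constant_incidence, 0.0)
        r = absolute_risk(20, 10, 0.0, hz, constant_mortality)
        assert r == pytest.approx(0.5 * (1 - np.exp(-0.2)), abs=1e-12)

    def test_additivity_of_the_integral(self, norwegian_like_rates):
        inc, mort = norwegian_like_rates
        hz = calibrate_baseline(inc, B)
        z = 1.3
        r_full, _ = absolute_risk_with_survival(30, 40, z, hz, mort)
        r1, s1 = absolute_risk_with_survival(30, 15, z, hz, mort)
        r2, _ = absolute_risk_with_survival(45, 25, z, hz, mort)
        assert r_full == pytest.approx(r1 + s1 * r2, abs=1e-12)

    def test_monotone_in_tau_and_z_and_bounded(self, norwegian_like_rates):
        inc, mort = norwegian_like_rates
        hz = calibrate_baseline(inc, B)
        risks = [absolute_risk(20, tau, 0.0, hz, mort) for tau in (10, 30, 60)]
        assert risks == sorted(risks)
        by_z = absolute_risk(20, 60, np.array([-1.0, 0.0, 1.0, 2.0]), hz, mort)
        assert np.all(np.diff(by_z) > 0)
        # mortality only lowers risk below the no-mortality bound
        lam_sum = hz.lambda0_at(np.arange(20, 80)).sum()
        assert by_z[1] <= 1 - np.exp(-lam_sum)
        no_mort = absolute_risk(20, 60, 0.0, hz, None)
        assert by_z[1] < no_mort

    def test_grid_out_of_range_error(self, norwegian_like_rates):
        inc, mort = norwegian_like_rates
        hz = calibrate_baseline(inc, 0.0)
        with pytest.raises(ValueError, match="span"):
            absolute_risk(20, 80, 0.0, hz, mort)


class TestRiskProfiles:
    def test_median_percentile_equals_z_zero_curve(self, norwegian_like_rates):
        inc, mort = norwegian_like_rates
        hz = calibrate_baseline(inc, B)
        prof = risk_profiles([0.5], hz, mort, 20, 80)
        assert prof.z_values[0] == pytest.approx(0.0, abs=1e-12)
        direct = [absolute_risk(20, a - 20, 0.0, hz, mort)
                  for a in prof.ages]
        np.testing.assert_allclose(prof.cumulative_risk[0], direct, atol=1e-12)

    def test_higher_percentile_dominates_everywhere(self, norwegian_like_rates):
        inc, mort = norwegian_like_rates
        hz = calibrate_baseline(inc, B)
        prof = risk_profiles([0.5, 0.99], hz, mort, 20, 80)
        diff = prof.cumulative_risk[1] - prof.cumulative_risk[0]
        assert np.all(diff >= 0)
        assert np.all(diff[prof.ages > 30] > 0)  # past the incidence onset
        assert np.all(np.diff(prof.cumulative_risk, axis=1) >= 0)
        assert prof.cumulative_risk.max() <= 1.0

    def test_lifetime_fold_ratios_match_reported_stratification(
            self, norwegian_like_rates):
        """99th vs median ~2.5x and 99th vs 1st ~6x lifetime risk to 80."""
        inc, mort = norwegian_like_rates
        hz = calibrate_baseline(inc, B)
        prof = risk_profiles([0.01, 0.5, 0.99], hz, mort, 20, 80)
        life = prof.cumulative_risk[:, -1]
        assert life[2] / life[1] == pytest.approx(2.5, rel=0.15)
        assert life[2] / life[0] == pytest.approx(6.0, rel=0.15)

    def test_bad_percentile_rejected(self, norwegian_like_rates):
        inc, mort = norwegian_like_rates
        hz = calibrate_baseline(inc, 0.0)
        with pytest.raises(ValueError):
            risk_profiles([0.0, 0.5], hz, mort, 20, 80)


class TestCaseCounts:
    def _cohort(self, z, status):
        import pandas as pd
        from bcprs.io import CohortTable
        n = len(z)
        return CohortTable(pd.DataFrame({
            "sample_id": [f"S{i}" for i in range(n)],
            "status": status,
            "entry_age": np.full(n, 30.0), "exit_age": np.full(n, 60.0),
            "event": np.asarray(status) == "case",
            "prs_raw": np.nan, "prs_z": z}))

    def test_cases_in_top_bin_are_counted_there(self):
        z = np.arange(100.0)
        status = ["case" if v >= 95 else "control" for v in z]
        counts = observed_case_counts(self._cohort(z, status), bins=10)
        assert counts[-1] == 5 and counts[:-1].sum() == 0

    def test_null_scores_spread_uniformly(self):
        rng = np.random.default_rng(5)
        n = 20_000
        z = rng.standard_normal(n)
        status = np.where(rng.random(n) < 0.1, "case", "control")
        counts = observed_case_counts(self._cohort(z, status), bins=10)
        expected = counts.sum() / 10
        # each decile within 4 binomial SDs of uniform
        se = np.sqrt(counts.sum() * 0.1 * 0.9)
        assert np.abs(counts - expected).max() < 4 * se

    def test_top_decile_about_twice_fifth_under_fitted_hr(
            self, norwegian_like_rates):
        """Case-count stratification implied by HR 1.494 per SD."""
        inc, mort = norwegian_like_rates
        cfg = SimulationConfig(n_samples=60_000, seed=8, true_b=B)
        rng = np.random.default_rng(8)
        z = rng.standard_normal(cfg.n_samples)
        cohort, _ = simulate_onset_cohort(z, B, inc, mort, cfg, rng=rng)
        counts = observed_case_counts(cohort, bins=10)
        assert counts[9] / counts[4] == pytest.approx(2.0, rel=0.30)
        assert np.all(np.argsort(counts)[-2:] >= 8)

    def test_expected_counts_match_simulated_within_mc_error(
            self, norwegian_like_rates):
        """Calibration-in-the-small: model-expected decile case counts
        agree with counts simulated from the same model."""
        inc, mort = norwegian_like_rates
        hz = calibrate_baseline(inc, B)
        rng = np.random.default_rng(9)
        n = 60_000
        z = rng.standard_normal(n)
        tab = RateTable("incidence", hz.ages, hz.ages + 1, hz.lambda0)
        onset = _sample_piecewise_times(tab, np.exp(B * z), rng)
        death = _sample_piecewise_times(mort, np.ones(n), rng)
        case = (onset >= 20) & (onset < 80) & (onset < death)
        edges = np.quantile(z, np.linspace(0, 1, 11)[1:-1])
        idx = np.searchsorted(edges, z, side="right")
        observed = np.bincount(idx[case], minlength=10)
        expected = expected_case_counts(z, hz, mort, 20, 80, bins=10)
        resid = (observed - expected) / np.sqrt(expected)
        assert np.abs(resid).max() < 4.0


def test_absolute_risk_model_estimator(norwegian_like_rates):
    from sklearn.base import clone

    inc, mort = norwegian_like_rates
    model = AbsoluteRiskModel(b=B).fit(inc, mort)
    r = model.predict(np.array([0.0, 2.326]), a=20, tau=60)
    assert 0 < r[0] < r[1] < 1
    prof = model.profiles([0.5, 0.99])
    assert prof.cumulative_risk.shape[0] == 2
    clone(model)
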