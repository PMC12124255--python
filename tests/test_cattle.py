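"""Pen biology: weights, heavyweight tail, grade-logit machinery, DMI."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit
from scipy.stats import norm

from feednet import cattle
from feednet.stochastic import stream

QG_LOCS = (-3.67, 0.82, 4.62)
YG_LOCS = (-3.59, -1.72, 0.15, 2.29)


class TestWeights:
    @pytest.mark.parametrize("w0,gain,dof", [(667.0, 1.32, 14), (431.0, 1.00, 42)])
    def test_linear_extension(self, w0, gain, dof):
        assert cattle.weights_at_endpoint(w0, gain, dof) == pytest.approx(w0 + gain * dof)

    def test_zero_extra_days_is_identity(self):
        assert cattle.weights_at_endpoint(500.0, 1.2, 0) == 500.0

    def test_negative_days_rejected(self):
        with pytest.raises(ValueError):
            cattle.weights_at_endpoint(500.0, 1.2, -7)

    def test_ep1_marginals_and_correlation(self, params, corrs):
        w = cattle.simulate_ep1_weights(params, corrs, 50_000, stream(21))
        assert w[:, 0].mean() == pytest.approx(667.0, abs=0.2)
        assert w[:, 1].mean() == pytest.approx(431.0, abs=0.2)
        assert w[:, 0].std() == pytest.approx(11.4, rel=0.02)
        assert np.corrcoef(w.T)[0, 1] == pytest.approx(corrs.fbw_hcw_ep1[0, 1], abs=0.02)

    def test_carcass_growth_identity_no_drift(self, params, corrs):
        # hcw(EPi) - hcw(EP1) must equal cdg * extra days exactly per pen
        w = cattle.simulate_ep1_weights(params, corrs, 100, stream(22))
        g = cattle.simulate_gains(params, corrs, 100, stream(23))
        for extra in (14, 28, 42):
            hcw_i = cattle.weights_at_endpoint(w[:, 1], g[:, 1], extra)
            np.testing.assert_allclose(hcw_i - w[:, 1], g[:, 1] * extra, rtol=1e-12)


class TestHeavyweightFraction:
    def test_at_threshold_is_half(self, params):
        assert cattle.heavyweight_fraction(476.0, params) == pytest.approx(0.5)

    def test_matches_normal_tail(self, params):
        # independent oracle: scipy.stats.norm upper tail
        for hcw in (431.0, 514.6, 476.0 + 38.6):
            expected = norm.sf((476.0 - hcw) / 38.6)
            assert cattle.heavyweight_fraction(hcw, params) == pytest.approx(expected, abs=1e-12)
        assert cattle.heavyweight_fraction(431.0, params) == pytest.approx(0.1218, abs=5e-4)
        assert cattle.heavyweight_fraction(514.6, params) == pytest.approx(0.8413, abs=1e-4)

    def test_non_decreasing_in_weight(self, params):
        hcw = np.linspace(380, 560, 50)
        frac = cattle.heavyweight_fraction(hcw, params)
        assert np.all(np.diff(frac) > 0)


class TestCumlogitDifferencing:
    def test_qg_central_proportions(self):
        props = cattle.cumlogits_to_proportions(QG_LOCS)
        np.testing.assert_allclose(props, [0.025, 0.669, 0.296, 0.010], atol=1e-3)
        assert props.sum() == pytest.approx(1.0, abs=1e-12)

    def test_yg_central_proportions(self):
        props = cattle.cumlogits_to_proportions(YG_LOCS)
        # exact oracle: differenced logistic CDF at the thresholds
        oracle = np.diff(np.concatenate([[0.0], expit(YG_LOCS), [1.0]]))
        np.testing.assert_allclose(props, oracle, atol=1e-12)
        # quoted medians are rounded simulation output, hence the wider band
        np.testing.assert_allclose(props, [0.027, 0.125, 0.385, 0.372, 0.092], atol=3e-3)

    def test_single_threshold_symmetry(self):
        np.testing.assert_allclose(cattle.cumlogits_to_proportions([0.0]), [0.5, 0.5])

    def test_non_monotone_rejected(self):
        with pytest.raises(ValueError):
            cattle.cumlogits_to_proportions([0.5, 0.1, 1.0])

    @given(st.lists(st.floats(-8, 8), min_size=1, max_size=6, unique=True))
    @settings(deadline=None)
    def test_valid_simplex_for_any_thresholds(self, logits):
        from hypothesis import assume

        logits = sorted(logits)
        assume(all(b > a for a, b in zip(logits, logits[1:])))
        props = cattle.cumlogits_to_proportions(logits)
        assert np.all(props >= 0) and np.all(props <= 1)
        assert props.sum() == pytest.approx(1.0, abs=1e-12)


class TestProportionalOddsShift:
    def test_zero_shift_is_identity(self):
        np.testing.assert_array_equal(cattle.shift_grade_logits(QG_LOCS, 0.0), QG_LOCS)

    def test_shifted_cumulative_probability(self):
        shifted = cattle.shift_grade_logits(QG_LOCS, 0.31)
        # Choice-or-better cumulative probability after the EP2 shift
        assert expit(shifted[1]) == pytest.approx(expit(1.13), abs=1e-12)
        assert expit(1.13) == pytest.approx(0.7558, abs=1e-4)

    def test_positive_shift_moves_mass_to_higher_grades(self):
        base = np.array(YG_LOCS)
        for beta in (0.43, 0.73, 1.31):
            p0 = cattle.cumlogits_to_proportions(base)
            p1 = cattle.cumlogits_to_proportions(cattle.shift_grade_logits(base, beta))
            # every cumulative "grade j or better" probability weakly increases
            assert np.all(np.cumsum(p1)[:-1] >= np.cumsum(p0)[:-1])


class TestGradeLogitSimulation:
    def test_zero_scales_return_locations(self, corrs):
        pairs = [(l, 0.0) for l in QG_LOCS]
        out = cattle.simulate_baseline_grade_logits(pairs, corrs.qg_intercepts, 50, stream(30))
        np.testing.assert_allclose(out, np.tile(QG_LOCS, (50, 1)), atol=1e-12)

    def test_rows_strictly_increasing(self, params, corrs):
        out = cattle.simulate_baseline_grade_logits(
            params.yg_intercepts, corrs.yg_intercepts, 20_000, stream(31))
        assert np.all(np.diff(out, axis=1) > 0)

    def test_median_row_matches_locations(self, params, corrs):
        out = cattle.simulate_baseline_grade_logits(
            params.qg_intercepts, corrs.qg_intercepts, 50_000, stream(32))
        np.testing.assert_allclose(np.median(out, axis=0), QG_LOCS, atol=0.01)

    def test_median_proportions_match_closed_form(self, params, corrs):
        logits = cattle.simulate_baseline_grade_logits(
            params.qg_intercepts, corrs.qg_intercepts, 50_000, stream(33))
        props = cattle.cumlogits_to_proportions(logits)
        med = np.median(props, axis=0)
        np.testing.assert_allclose(med, cattle.cumlogits_to_proportions(QG_LOCS), atol=0.004)

    def test_increasing_locations_required(self, corrs):
        with pytest.raises(ValueError):
            cattle.simulate_baseline_grade_logits(
                [(0.82, 0.3), (-3.67, 0.3), (4.62, 0.3)], corrs.qg_intercepts, 5, stream(0))

    def test_repair_counter_wired(self, corrs):
        # huge scales force threshold crossings, exercising redraw + fallback
        counter = cattle.RepairCounter()
        pairs = [(-0.1, 5.0), (0.0, 5.0), (0.1, 5.0)]
        out = cattle.simulate_baseline_grade_logits(
            pairs, corrs.qg_intercepts, 500, stream(34), max_redraws=2, counter=counter)
        assert np.all(np.diff(out, axis=1) > 0)
        assert counter.redraws > 0 and counter.fallback_sorts > 0


class TestDMI:
    def test_moments_and_reuse(self, params):
        x = cattle.simulate_dmi(params, 50_000, stream(40))
        assert x.mean() == pytest.approx(10.5, abs=0.01)
        assert x.std() == pytest.approx(0.58, rel=0.02)

    def test_degenerate_sd(self, params):
        import dataclasses
        from feednet.params import MeanSD
        p = dataclasses.replace(params, dmi=MeanSD(10.5, 0.0))
        assert np.all(cattle.simulate_dmi(p, 10, stream(41)) == 10.5)
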