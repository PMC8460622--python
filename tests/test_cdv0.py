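import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

from garddr.cdv0 import (
    Cdv0Estimate,
    InterpolationBracket,
    cdv0_from_model,
    cdv0_linear_interpolation,
    compare_estimators,
    needs_smoothing,
    running_median,
)
from garddr.data import DoseResponseDataset
from garddr.model import fit_log_logistic, log_logistic
from garddr.simulate import SimulationSpec, simulate_dataset


class _FixedFit:
    """Stand-in results object with prescribed 4PL parameters."""

    def __init__(self, b, c, d, e, converged=True):
        self.b, self.c, self.d, self.e = b, c, d, e
        self.converged = converged
        self.cov_bdu = None


class TestModelBasedEstimate:
    def test_symmetric_curve_crosses_at_midpoint(self):
        est = cdv0_from_model(_FixedFit(-1, -1, 1, 10), ci_level=None)
        assert est.value == pytest.approx(10.0, rel=1e-12)

    def test_closed_form_example(self):
        # x = 10 * ((1.5/1) - 1) ** (-1/2) = 10 / sqrt(0.5)
        est = cdv0_from_model(_FixedFit(-2, -1, 0.5, 10), ci_level=None)
        assert est.value == pytest.approx(14.1421356237309505, rel=1e-12)

    def test_upper_asymptote_below_threshold_is_censored(self):
        est = cdv0_from_model(_FixedFit(-1, -1, -0.2, 10), ci_level=None)
        assert est.is_censored and est.censored == "NS"

    def test_unconverged_fit_is_censored_with_note(self):
        est = cdv0_from_model(_FixedFit(-1, -1, 1, 10, converged=False), ci_level=None)
        assert est.is_censored
        assert "converged" in est.notes

    def test_closed_form_agrees_with_bisection_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            b = -float(rng.uniform(0.2, 5.0))
            c = -float(rng.uniform(0.2, 2.0))
            d = float(rng.uniform(0.05, 2.0))
            e = float(np.exp(rng.uniform(np.log(0.5), np.log(500.0))))
            est = cdv0_from_model(_FixedFit(b, c, d, e), ci_level=None)
            root = brentq(
                lambda x: log_logistic(x, b, c, d, e), 1e-12, 1e12, xtol=1e-15, rtol=1e-14
            )
            assert est.value == pytest.approx(root, rel=1e-8)


class TestConfidenceInterval:
    def test_zero_noise_interval_collapses_onto_the_estimate(self, noiseless_dataset):
        res = fit_log_logistic(noiseless_dataset)
        est = cdv0_from_model(res)
        assert est.value == pytest.approx(20.0, rel=1e-4)
        assert est.ci_low == pytest.approx(est.value, rel=1e-3)
        assert est.ci_high == pytest.approx(est.value, rel=1e-3)

    def test_interval_brackets_the_estimate(self, grid9):
        for seed in range(20):
            ds = simulate_dataset(
                SimulationSpec(b=-1.5, c=-1, d=1, e=20, noise_sd=0.1, grid=grid9, seed=seed)
            )
            est = cdv0_from_model(fit_log_logistic(ds))
            if est.value is None or est.ci_low is None or est.ci_high is None:
                continue
            assert est.ci_low <= est.value <= est.ci_high


class TestRunningMedian:
    def test_hand_computed_example(self):
        out = running_median([-1, 1, -0.5, 0.8, 0.9], window=3)
        np.testing.assert_allclose(out, [-1, -0.5, 0.8, 0.8, 0.9])

    def test_monotone_sequence_unchanged(self):
        seq = [-1.0, -0.5, 0.0, 0.5, 1.0, 1.5]
        np.testing.assert_allclose(running_median(seq), seq)

    def test_constant_sequence_unchanged(self):
        np.testing.assert_allclose(running_median([0.3] * 5), [0.3] * 5)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            running_median([1.0, 2.0, 3.0, 4.0], window=4)

    def test_output_length_matches_input(self):
        assert running_median(np.arange(7.0), window=5).size == 7


class TestLinearInterpolation:
    def test_hand_evaluated_crossing(self):
        ds = DoseResponseDataset.from_arrays(
            "h", [1, 3, 9, 27], [-1, 1, 1.2, 1.3], control_dv=-1.0
        )
        est = cdv0_linear_interpolation(ds)
        assert est.value == pytest.approx(2.0)

    def test_symmetric_bracket_midpoint(self):
        ds = DoseResponseDataset.from_arrays(
            "s", [5, 10, 20, 40], [-0.9, -0.5, 0.5, 0.9], control_dv=-1.0
        )
        assert cdv0_linear_interpolation(ds).value == pytest.approx(15.0)

    def test_noiseless_4pl_on_assay_grid_lands_near_truth(self, grid9):
        ds = simulate_dataset(
            SimulationSpec(b=-1, c=-1, d=1, e=20, noise_sd=0.0, grid=grid9, seed=0)
        )
        est = cdv0_linear_interpolation(ds)
        lo = grid9[grid9 < 20].max()
        hi = grid9[grid9 >= 20].min()
        assert lo <= est.value <= hi
        assert est.value == pytest.approx(20.0, rel=0.10)

    def test_all_negative_is_ns(self, grid9):
        ds = DoseResponseDataset.from_arrays(
            "neg", grid9, np.linspace(-1, -0.2, grid9.size), control_dv=-1.0
        )
        est = cdv0_linear_interpolation(ds)
        assert est.censored == "NS"

    def test_positive_lowest_concentration_is_left_censored(self, grid9):
        ds = DoseResponseDataset.from_arrays(
            "pos", grid9, np.linspace(0.1, 1.0, grid9.size), control_dv=-1.0
        )
        est = cdv0_linear_interpolation(ds)
        assert est.censored == "<cmin"

    def test_censoring_matches_brute_force_scan(self, grid9):
        rng = np.random.default_rng(5)
        for _ in range(200):
            dvs = rng.uniform(-1.5, 1.5, grid9.size)
            ds = DoseResponseDataset.from_arrays("r", grid9, dvs, control_dv=-1.0)
            smoothed = running_median(dvs, 3)
            est = cdv0_linear_interpolation(ds, smooth=True)
            ns_expected = not np.any(smoothed >= 0.0)
            assert (est.censored == "NS") == ns_expected

    def test_scale_equivariance(self, grid9):
        ds = simulate_dataset(
            SimulationSpec(b=-1.5, c=-1, d=1, e=30, noise_sd=0.05, grid=grid9, seed=9)
        )
        for k in (0.1, 7.3):
            scaled = DoseResponseDataset.from_arrays(
                "k", ds.concentrations * k, ds.dvs, control_dv=ds.control_dv
            )
            est0 = cdv0_linear_interpolation(ds)
            estk = cdv0_linear_interpolation(scaled)
            assert estk.value == pytest.approx(k * est0.value, rel=1e-12)
            ll0 = cdv0_from_model(fit_log_logistic(ds), ci_level=None)
            llk = cdv0_from_model(fit_log_logistic(scaled), ci_level=None)
            assert llk.value == pytest.approx(k * ll0.value, rel=1e-4)


@settings(deadline=None, derandomize=True, max_examples=200)
@given(
    c_minus=st.floats(0.01, 1e4),
    width=st.floats(1e-3, 10.0),
    dv_minus=st.floats(-5.0, -1e-6),
    dv_plus=st.floats(0.0, 5.0),
)
def test_bracket_interpolation_is_the_exact_linear_crossing(c_minus, width, dv_minus, dv_plus):
    """The two-point formula returns exactly where the straight line through
    the bracket points crosses zero (algebraic identity)."""
    c_plus = c_minus * (1 + width)
    bracket = InterpolationBracket(c_minus, dv_minus, c_plus, dv_plus)
    x = bracket.interpolate()
    # the line through the two points evaluates to ~0 at x
    slope = (dv_plus - dv_minus) / (c_plus - c_minus)
    assert dv_minus + slope * (x - c_minus) == pytest.approx(0.0, abs=1e-9 * abs(dv_minus))
    assert c_minus <= x <= c_plus


def test_estimators_agree_on_dense_noiseless_data():
    grid = np.geomspace(0.5, 500, 24)
    ds = simulate_dataset(SimulationSpec(b=-1.2, c=-1, d=1, e=20, noise_sd=0, grid=grid, seed=0))
    ll = cdv0_from_model(fit_log_logistic(ds), ci_level=None).value
    li = cdv0_linear_interpolation(ds).value
    assert abs(ll - li) / ll < 0.02


class TestCompareEstimators:
    def test_clean_sigmoid_unflagged_and_concordant(self, grid9):
        datasets = [
            simulate_dataset(
                SimulationSpec(b=-1.5, c=-1, d=1, e=50, noise_sd=0.05, grid=grid9, seed=s),
                chemical_id=f"s{s}",
            )
            for s in range(5)
        ]
        table = compare_estimators(datasets)
        assert not table["flagged"].any()
        rel = (table["cdv0_ll_uM"] - table["cdv0_interp_uM"]).abs() / table["cdv0_ll_uM"]
        assert (rel < 0.15).all()

    def test_flat_data_both_censored_unflagged(self, flat_dataset):
        table = compare_estimators([flat_dataset])
        assert table.loc[0, "cdv0_ll_censored"] == "NS"
        assert table.loc[0, "cdv0_interp_censored"] == "NS"
        assert not table.loc[0, "flagged"]

    def test_two_phase_curve_raises_discordance_flag(self, grid9):
        # early rise to a positive plateau, then a second increase: the local
        # interpolation finds the lower crossing, the 4PL a higher one
        ds = simulate_dataset(
            SimulationSpec(
                b=-3, c=-1, d=1.4, e=250, noise_sd=0.0, grid=grid9,
                contamination="two_phase", seed=0,
            ),
            chemical_id="plateau",
        )
        table = compare_estimators([ds])
        assert table.loc[0, "flagged"]
        interp = table.loc[0, "cdv0_interp_uM"]
        ll = table.loc[0, "cdv0_ll_uM"]
        if interp is not None and ll is not None and not math.isnan(ll):
            assert interp < ll


class TestEstimateInvariants:
    def test_interval_must_bracket_value(self):
        with pytest.raises(ValueError):
            Cdv0Estimate(value=10.0, method="log_logistic", ci_low=12.0, ci_high=15.0)

    def test_censored_estimate_may_keep_lower_bound_only(self):
        est = Cdv0Estimate(
            value=None, method="log_logistic", ci_low=406.0, ci_high=None, censored="NS"
        )
        assert est.display() == "NS (406, NA)"

    def test_needs_smoothing_triggers_on_sign_chatter(self):
        assert needs_smoothing([-1, 0.2, -0.5, 0.8, 0.9])
        assert not needs_smoothing([-1, -0.5, 0.2, 0.8, 0.9])
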