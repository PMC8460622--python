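import numpy as np
import pytest

from garddr.data import DoseResponseDataset, InsufficientDataError
from garddr.model import (
    LogLogisticDoseResponse,
    fit_flat,
    fit_log_logistic,
    log_logistic,
    no_effect_test,
)
from garddr.simulate import SimulationSpec, simulate_dataset


class TestPredict:
    def test_midpoint_halves_the_span(self):
        # at x = e the logistic term is 1/2: midpoint of (c, d)
        assert log_logistic(10.0, b=-1, c=-1, d=1, e=10) == pytest.approx(0.0, abs=1e-12)

    def test_lower_asymptote_limit(self):
        assert log_logistic(1e-9, b=-1, c=-1, d=1, e=10) == pytest.approx(-1.0, abs=1e-6)

    def test_against_arbitrary_precision_evaluation(self):
        # frozen from a 30-digit symbolic evaluation of the 4PL at these inputs
        assert log_logistic(25.0, b=-2, c=-0.8, d=1.4, e=50) == pytest.approx(
            -0.36, abs=1e-12
        )

    def test_nonpositive_concentration_is_a_domain_error(self):
        with pytest.raises(ValueError):
            log_logistic(0.0, b=-1, c=-1, d=1, e=10)
        with pytest.raises(ValueError):
            log_logistic(-5.0, b=-1, c=-1, d=1, e=10)


class TestFit:
    def test_exact_recovery_on_noiseless_data(self, noiseless_dataset):
        res = fit_log_logistic(noiseless_dataset)
        assert res.converged
        assert res.rss < 1e-10
        assert res.b == pytest.approx(-1.5, rel=1e-4)
        assert res.d == pytest.approx(1.0, rel=1e-4)
        assert res.e == pytest.approx(20.0, rel=1e-4)
        assert res.c == noiseless_dataset.control_dv  # fixed exactly

    def test_constant_dvs_give_degenerate_unconverged_fit(self, grid9):
        ds = DoseResponseDataset.from_arrays(
            "const", grid9, np.full(grid9.size, -1.0), control_dv=-1.0
        )
        res = fit_log_logistic(ds)
        assert not res.converged

    def test_too_few_distinct_concentrations(self):
        ds = DoseResponseDataset.from_arrays(
            "tiny", [1.0, 1.0, 2.0], [-1.0, -0.9, 0.5], control_dv=-1.0
        )
        with pytest.raises(InsufficientDataError):
            fit_log_logistic(ds)

    def test_matches_grid_search_oracle_on_noisy_data(self, grid9):
        """Multi-start least squares finds the optimum an exhaustive
        (twice-refined) grid search over (b, d, e) locates."""
        spec = SimulationSpec(b=-2.0, c=-1.0, d=1.2, e=50.0, noise_sd=0.1, grid=grid9, seed=11)
        ds = simulate_dataset(spec)
        res = fit_log_logistic(ds)

        x, y, c = ds.concentrations, ds.dvs, ds.control_dv

        def rss_of(b, d, e):
            return float(np.sum((log_logistic(x, b, c, d, e) - y) ** 2))

        # coarse grid, then two refinements around the incumbent
        b_grid = -np.geomspace(0.2, 10, 25)
        d_grid = np.linspace(0.0, 2.5, 25)
        e_grid = np.geomspace(1.0, 1000.0, 25)
        best = None
        for _ in range(3):
            for b in b_grid:
                for d in d_grid:
                    for e in e_grid:
                        r = rss_of(b, d, e)
                        if best is None or r < best[0]:
                            best = (r, b, d, e)
            _, b0, d0, e0 = best
            b_grid = b0 * np.geomspace(1 / 1.5, 1.5, 15)
            d_grid = np.linspace(d0 - 0.2, d0 + 0.2, 15)
            e_grid = e0 * np.geomspace(1 / 1.5, 1.5, 15)
        grid_rss, gb, gd, ge = best
        assert res.rss <= grid_rss * (1 + 1e-6)
        assert res.b == pytest.approx(gb, rel=0.15)
        assert res.d == pytest.approx(gd, abs=0.1)
        assert res.e == pytest.approx(ge, rel=0.15)

    def test_fitted_curve_is_monotone_nondecreasing(self, grid9):
        for seed in range(10):
            ds = simulate_dataset(
                SimulationSpec(noise_sd=0.15, grid=grid9, seed=seed), chemical_id="m"
            )
            res = fit_log_logistic(ds)
            if not res.converged:
                continue
            xs = np.geomspace(0.01, 5000, 200)
            ys = res.predict(xs)
            assert np.all(np.diff(ys) >= -1e-12)

    def test_midpoint_estimate_stays_within_quarter_relative_error(self, grid9):
        errs = []
        for seed in range(200):
            ds = simulate_dataset(
                SimulationSpec(b=-1.5, c=-1, d=1, e=20, noise_sd=0.1, grid=grid9, seed=seed)
            )
            errs.append(abs(fit_log_logistic(ds).e - 20.0) / 20.0)
        assert np.median(errs) <= 0.25

    def test_from_dataframe_constructor(self):
        import pandas as pd

        df = pd.DataFrame(
            {"concentration_uM": [1, 3, 9, 27, 81], "dv": [-1, -0.8, 0.0, 0.8, 1.0]}
        )
        res = LogLogisticDoseResponse.from_dataframe(df, chemical_id="df").fit()
        assert res.converged
        assert "df" in res.summary()


class TestFlatFit:
    def test_hand_arithmetic(self):
        ds = DoseResponseDataset.from_arrays("h", [1, 2, 4], [-1, 0, 1], control_dv=-2.0)
        value, rss = fit_flat(ds)
        assert value == pytest.approx(0.0)
        assert rss == pytest.approx(2.0)

    def test_single_point(self):
        with pytest.warns(UserWarning):
            ds = DoseResponseDataset.from_arrays("s", [5.0], [0.3], control_dv=-1.0)
        value, rss = fit_flat(ds)
        assert value == pytest.approx(0.3)
        assert rss == 0.0

    def test_nesting_flat_rss_dominates_4pl_rss(self, grid9):
        # the flat line is a boundary case of the constrained 4PL
        for seed in range(25):
            rng = np.random.default_rng(seed)
            shape = rng.choice(["sig", "flat"])
            if shape == "sig":
                ds = simulate_dataset(
                    SimulationSpec(noise_sd=0.2, grid=grid9, seed=seed), chemical_id="n"
                )
            else:
                ds = DoseResponseDataset.from_arrays(
                    "n", grid9, -1 + rng.normal(0, 0.2, grid9.size), control_dv=-1.0
                )
            _, flat_rss = fit_flat(ds)
            assert fit_log_logistic(ds).rss <= flat_rss + 1e-9


class TestNoEffect:
    def test_strong_sigmoid_is_highly_significant(self, grid9):
        ds = simulate_dataset(
            SimulationSpec(b=-1.5, c=-1, d=1, e=50, noise_sd=0.05, grid=grid9, seed=2)
        )
        assert no_effect_test(ds).p_value < 1e-3

    def test_flat_noise_rarely_significant(self, grid9):
        n_ok = 0
        reps = 200
        for seed in range(reps):
            rng = np.random.default_rng(1_000 + seed)
            ds = DoseResponseDataset.from_arrays(
                "f", grid9, -1.0 + rng.normal(0, 0.05, grid9.size), control_dv=-1.0
            )
            n_ok += no_effect_test(ds).p_value > 0.05
        assert n_ok / reps >= 0.90

    def test_degenerate_fit_reports_no_effect(self, grid9):
        ds = DoseResponseDataset.from_arrays(
            "c", grid9, np.full(grid9.size, -1.0), control_dv=-1.0
        )
        result = no_effect_test(ds)
        assert result.lr_statistic == 0.0
        assert result.p_value == 1.0
        assert not result.converged

    def test_statistic_nonnegative_and_p_in_unit_interval(self, flat_dataset):
        result = no_effect_test(flat_dataset)
        assert result.lr_statistic >= 0.0
        assert 0.0 <= result.p_value <= 1.0
        assert result.df == 2
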