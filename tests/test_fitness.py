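"""Selection-coefficient estimation: trajectories, likelihoods, censoring."""

import math

import numpy as np
import pytest
import sympy
from hypothesis import given, settings
from hypothesis import strategies as st

from dupfit.fitness import (
    AssayConfig,
    CompetitionCounts,
    SelectionEstimate,
    call_effect,
    censor_competition,
    detection_limit,
    estimate_ne,
    estimate_resolution,
    estimate_s_closed_form,
    estimate_s_mle,
    fit_well,
    log_likelihood,
    logistic_trajectory,
)


class TestLogisticTrajectory:
    def test_neutral_holds_frequency(self):
        assert logistic_trajectory(0.3, 0.0, 57.0) == pytest.approx(0.3)

    def test_odds_double_at_st_log2(self):
        # odds multiply by e^{st}: s t = ln 2 turns 1:1 into 2:1
        assert logistic_trajectory(0.5, math.log(2) / 20, 20) == pytest.approx(
            2 / 3, abs=1e-12
        )

    def test_matches_numerical_ode_integration(self):
        # forward Euler on dR/dt = s R (1-R) at step 1e-4
        s, r = 0.03466, 0.5
        for _ in range(200_000):
            r += 1e-4 * s * r * (1 - r)
        assert logistic_trajectory(0.5, s, 20) == pytest.approx(r, abs=1e-6)

    def test_strong_negative_s_goes_extinct(self):
        assert logistic_trajectory(0.9, -0.1, 1e6) == pytest.approx(0.0, abs=1e-300)

    def test_rejects_degenerate_start(self):
        for r0 in (0.0, 1.0, -0.1):
            with pytest.raises(ValueError):
                logistic_trajectory(r0, 0.1, 10)


class TestLogLikelihood:
    def test_all_red_single_timepoint(self):
        counts = CompetitionCounts("w", (10.0,), (5,), (0,))
        r_t = logistic_trajectory(0.4, 0.02, 10.0)
        assert log_likelihood(counts, 0.4, 0.02) == pytest.approx(5 * math.log(r_t))

    def test_symmetric_counts_under_fair_coin(self):
        counts = CompetitionCounts("w", (0.0, 1.0), (3, 1), (1, 3))
        const = math.log(math.comb(4, 3)) + math.log(math.comb(4, 1))
        assert log_likelihood(counts, 0.5, 0.0) == pytest.approx(
            8 * math.log(0.5) + const
        )

    def test_matches_arbitrary_precision_product(self):
        # independent oracle: the binomial product evaluated with sympy
        counts = CompetitionCounts("w", (20.0, 40.0), (123, 456), (877, 544))
        R0, s = 0.11, 0.07
        total = sympy.Integer(0)
        for t, r, g in zip(counts.timepoints, counts.red, counts.green):
            n = r + g
            Rt = sympy.Rational(11, 100) * sympy.exp(sympy.Float(s, 30) * t) / (
                sympy.Rational(89, 100)
                + sympy.Rational(11, 100) * sympy.exp(sympy.Float(s, 30) * t)
            )
            total += (
                sympy.log(sympy.binomial(n, r))
                + r * sympy.log(Rt)
                + (n - r) * sympy.log(1 - Rt)
            )
        assert log_likelihood(counts, R0, s) == pytest.approx(
            float(total.evalf(30)), abs=1e-8
        )


class TestClosedForm:
    def test_flat_counts_give_zero(self):
        counts = CompetitionCounts("w", (20.0, 40.0), (100, 100), (100, 100))
        assert estimate_s_closed_form(counts).s == 0.0

    def test_doubling_ratio(self):
        counts = CompetitionCounts("w", (20.0, 40.0), (100, 200), (100, 100))
        est = estimate_s_closed_form(counts)
        assert est.s == pytest.approx(math.log(2) / 20, abs=1e-12)
        # grid-search oracle over the profile likelihood (R0 profiled out
        # by bounded 1-D optimization at every grid point)
        from scipy.optimize import minimize_scalar

        grid = np.arange(est.s - 5e-4, est.s + 5e-4, 1e-5)
        lls = [
            -minimize_scalar(
                lambda r0: -log_likelihood(counts, r0, s),
                bounds=(1e-6, 1 - 1e-6),
                method="bounded",
            ).fun
            for s in grid
        ]
        assert grid[int(np.argmax(lls))] == pytest.approx(est.s, abs=2e-5)

    def test_antisymmetric_under_channel_swap(self):
        counts = CompetitionCounts("w", (20.0, 40.0), (100, 200), (100, 100))
        swapped = CompetitionCounts("w", (20.0, 40.0), (100, 100), (100, 200))
        assert estimate_s_closed_form(swapped).s == pytest.approx(
            -estimate_s_closed_form(counts).s
        )

    def test_zero_count_demands_censoring(self):
        counts = CompetitionCounts("w", (20.0, 40.0), (0, 10), (100, 100))
        with pytest.raises(ValueError, match="censor"):
            estimate_s_closed_form(counts)


class TestMLE:
    def test_equals_closed_form_at_two_timepoints(self):
        counts = CompetitionCounts("w", (20.0, 40.0), (137, 264), (452, 307))
        cf = estimate_s_closed_form(counts)
        ml = estimate_s_mle(counts)
        assert ml.converged
        assert ml.s == pytest.approx(cf.s, abs=1e-8)
        assert ml.R0_hat == pytest.approx(cf.R0_hat, abs=1e-8)

    def test_exact_log_linear_three_timepoints(self):
        # r/g doubling every 20 generations: s = ln2/20 exactly, and OLS on
        # log ratios is the MLE because all totals are equal
        counts = CompetitionCounts(
            "w", (0.0, 20.0, 40.0), (100, 200, 400), (100, 100, 100)
        )
        est = estimate_s_mle(counts)
        assert est.converged
        assert est.s == pytest.approx(math.log(2) / 20, abs=1e-6)

    def test_matches_statsmodels_glm(self):
        import statsmodels.api as sm

        counts = CompetitionCounts(
            "w", (0.0, 20.0, 40.0), (140, 220, 390), (820, 731, 600)
        )
        t = np.array(counts.timepoints)
        X = sm.add_constant(t)
        fit = sm.GLM(
            np.column_stack([counts.red, counts.green]), X,
            family=sm.families.Binomial(),
        ).fit()
        est = estimate_s_mle(counts)
        assert est.s == pytest.approx(fit.params[1], abs=1e-8)
        assert est.se == pytest.approx(fit.bse[1], rel=1e-4)

    def test_parameter_recovery(self):
        # mean of the estimator over many simulated wells matches truth
        rng = np.random.default_rng(4)
        true_s, n = -0.013, 50_000
        p = logistic_trajectory(0.5, true_s, np.array([20.0, 40.0]))
        r = rng.binomial(n, p, size=(1000, 2))
        s_hat = (np.log(r[:, 1] / (n - r[:, 1])) - np.log(r[:, 0] / (n - r[:, 0]))) / 20
        se = np.std(s_hat, ddof=1) / math.sqrt(1000)
        assert abs(np.mean(s_hat) - true_s) < 3 * se


class TestCensoring:
    def test_depleted_red_reported_below_bound(self):
        counts = CompetitionCounts("w", (20.0, 40.0), (500, 20), (49500, 49980))
        est = censor_competition(counts, AssayConfig())
        assert est.status == "censored_low"
        assert est.s == -0.3

    def test_tiny_totals_mean_equally_lethal(self):
        counts = CompetitionCounts("w", (20.0, 40.0), (100, 10), (100, 20))
        est = censor_competition(counts, AssayConfig())
        assert est.status == "equally_lethal" and est.s == 0.0

    def test_equally_lethal_takes_precedence(self):
        # total below the floor AND a channel below the floor: lethality wins
        counts = CompetitionCounts("w", (20.0,), (5, ), (30,))
        est = censor_competition(counts, AssayConfig())
        assert est.status == "equally_lethal"

    def test_boundary_count_passes_through(self):
        counts = CompetitionCounts("w", (20.0, 40.0), (80, 60), (49920, 49940))
        out = censor_competition(counts, AssayConfig())
        assert isinstance(out, CompetitionCounts)

    def test_channel_floor_applies_at_every_timepoint(self):
        counts = CompetitionCounts("w", (20.0, 40.0), (30, 80), (49970, 49920))
        est = censor_competition(counts, AssayConfig())
        assert est.status == "censored_low"

    def test_fit_well_never_sees_zero_counts(self):
        counts = CompetitionCounts("w", (20.0, 40.0), (60, 0), (49940, 50000))
        est = fit_well(counts)
        assert est.status == "censored_low"


class TestDetectionLimit:
    def test_stated_rule_gives_minus_0p27(self):
        s = detection_limit(AssayConfig(), R0=0.5, t_final=40.0)
        closed = (math.log(1 / 49999)) / 40  # log-odds inversion
        assert s == pytest.approx(closed, abs=1e-6)
        assert s == pytest.approx(-0.2705, abs=1e-4)

    def test_threshold_at_starting_frequency(self):
        s = detection_limit(AssayConfig(detect_denominator=2), R0=0.5, t_final=40.0)
        assert s == pytest.approx(0.0, abs=1e-6)

    def test_halving_time_doubles_magnitude(self):
        s40 = detection_limit(AssayConfig(), R0=0.5, t_final=40.0)
        s20 = detection_limit(AssayConfig(), R0=0.5, t_final=20.0)
        assert s20 == pytest.approx(2 * s40, abs=1e-5)


class TestResolution:
    def test_paper_scale_sd(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(0, 1, 64)
        vals = (vals - vals.mean()) / vals.std(ddof=1) * 0.0017
        res = estimate_resolution(vals)
        assert res.sd_s == pytest.approx(0.0017, abs=1e-12)
        assert res.resolution == pytest.approx(0.003332, abs=1e-6)

    def test_identical_inputs_have_zero_spread(self):
        with pytest.raises(ValueError):
            estimate_resolution([0.001])
        res = estimate_resolution([0.001, 0.001, 0.001])
        assert res.sd_s == 0.0 and res.resolution == 0.0

    def test_hand_computed_pair(self):
        res = estimate_resolution([-0.001, 0.001])
        assert res.mean_s == pytest.approx(0.0)
        assert res.sd_s == pytest.approx(0.0014142, abs=1e-6)
        assert res.resolution == pytest.approx(0.0027719, abs=1e-6)

    @settings(deadline=None, max_examples=30)
    @given(
        st.lists(st.floats(-0.01, 0.01), min_size=3, max_size=20),
        st.floats(-0.1, 0.1),
    )
    def test_shift_invariance(self, vals, shift):
        base = estimate_resolution(vals)
        moved = estimate_resolution([v + shift for v in vals])
        assert moved.resolution == pytest.approx(base.resolution, abs=1e-12)


class TestCallEffect:
    def test_consistent_deleterious(self):
        reps = [SelectionEstimate("a", -0.013), SelectionEstimate("b", -0.015)]
        assert call_effect(reps) == "deleterious"

    def test_small_effects_not_called(self):
        reps = [SelectionEstimate("a", 0.002), SelectionEstimate("b", -0.001)]
        assert call_effect(reps) == "no_detectable_effect"

    def test_sign_disagreement_is_inconsistent(self):
        reps = [SelectionEstimate("a", -0.006), SelectionEstimate("b", 0.006)]
        assert call_effect(reps) == "inconsistent"

    def test_censored_replicate_forces_deleterious(self):
        reps = [
            SelectionEstimate("a", -0.3, status="censored_low"),
            SelectionEstimate("b", -0.001),
        ]
        assert call_effect(reps) == "deleterious"

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError):
            call_effect([SelectionEstimate("a", -0.1)])


class TestNe:
    def test_single_cell_bottleneck(self):
        assert estimate_ne(2.0, 1.0, 2.0) == pytest.approx(1.0)

    def test_geometric_series_ten_doublings(self):
        n_b = 1000.0
        ne = estimate_ne(n_b * 1024, 1.0, 1024.0)
        assert ne == pytest.approx(10 * n_b / (2 - 2**-9))

    def test_assay_configuration_order_of_magnitude(self):
        ne = estimate_ne(2e8, 0.32, 1024)
        assert ne == pytest.approx(3.13e5, rel=0.01)
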