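"""Split-line (broken-stick) fitter: exact reconstruction, oracle
equivalence and breakpoint-profile properties."""
import numpy as np
import pytest

import npartition as nv

from conftest import TRUE_SPLITLINE


def hinge_ols_oracle(x, y, c):
    """Independent brute-force solution of the hinge regression at a fixed
    breakpoint: explicitly assembled normal equations X'X b = X'y."""
    x = np.asarray(x, float)
    X = np.column_stack([np.ones_like(x), x, np.maximum(x - c, 0.0)])
    beta = np.linalg.solve(X.T @ X, X.T @ np.asarray(y, float))
    resid = y - X @ beta
    return beta, float(resid @ resid)


class TestExactReconstruction:
    def test_noise_free_printed_equation(self, noise_free_milk):
        """Noise-free data from the true model at the fed dose levels gives
        back (20.5, 0.0029, -0.0235, 350) when 350 is a candidate."""
        x, y = noise_free_milk
        fit = nv.fit_splitline(x, y, candidates=np.arange(180, 451, 10))
        assert fit.breakpoint == 350.0
        assert fit.intercept == pytest.approx(20.5, abs=1e-9)
        assert fit.slope_below == pytest.approx(0.0029, abs=1e-12)
        assert fit.slope_above == pytest.approx(-0.0235, abs=1e-12)
        assert fit.sse == pytest.approx(0.0, abs=1e-18)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.p_value_slope_change < 1e-10

    def test_default_grid_contains_350_and_recovers(self, noise_free_milk):
        x, y = noise_free_milk
        fit = nv.fit_splitline(x, y)
        assert fit.breakpoint == 350.0

    def test_predictions_at_key_doses(self, noise_free_milk):
        x, y = noise_free_milk
        fit = nv.fit_splitline(x, y)
        assert nv.predict_splitline(fit, 0) == pytest.approx(20.5)
        assert nv.predict_splitline(fit, 350) == pytest.approx(21.515)
        assert nv.predict_splitline(fit, 690) == pytest.approx(13.525)

    def test_continuity_at_breakpoint(self, noise_free_milk):
        x, y = noise_free_milk
        fit = nv.fit_splitline(x, y)
        eps = 1e-9
        below = nv.predict_splitline(fit, fit.breakpoint - eps)
        above = nv.predict_splitline(fit, fit.breakpoint + eps)
        assert below == pytest.approx(above, abs=1e-6)


class TestOracleEquivalence:
    def test_singleton_candidate_equals_normal_equations(self):
        """With one candidate the profiled fit is plain hinge OLS; it must
        match the brute-force normal-equations solution."""
        rng = np.random.default_rng(7)
        x = rng.uniform(0, 700, 40)
        y = 20 + 0.01 * x + rng.normal(0, 2, 40)
        c0 = 300.0
        fit = nv.fit_splitline(x, y, candidates=[c0], refine=False)
        beta, sse = hinge_ols_oracle(x, y, c0)
        assert fit.intercept == pytest.approx(beta[0], rel=1e-8)
        assert fit.slope_below == pytest.approx(beta[1], rel=1e-8)
        assert fit.slope_above == pytest.approx(beta[1] + beta[2], rel=1e-8)
        assert fit.sse == pytest.approx(sse, rel=1e-8)

    def test_many_random_instances(self):
        """Profile-OLS equals the oracle at every candidate on 50 random
        small instances."""
        rng = np.random.default_rng(12345)
        for _ in range(50):
            n = int(rng.integers(10, 50))
            x = rng.uniform(0, 700, n)
            y = rng.normal(20, 3, n) + 0.005 * x
            c = float(rng.uniform(np.sort(x)[2], np.sort(x)[-3]))
            fit = nv.fit_splitline(x, y, candidates=[c], refine=False)
            beta, sse = hinge_ols_oracle(x, y, c)
            np.testing.assert_allclose(
                [fit.intercept, fit.slope_below, fit.slope_above],
                [beta[0], beta[1], beta[1] + beta[2]],
                rtol=1e-8, atol=1e-10,
            )
            assert fit.sse == pytest.approx(sse, rel=1e-8, abs=1e-10)


class TestProfileProperties:
    def test_selected_sse_is_minimal_over_candidates(self):
        rng = np.random.default_rng(99)
        x = np.repeat(np.array([0.0, 88, 176, 351, 450, 600, 690]), 5)
        y = np.array([nv.predict_true_milk(v, TRUE_SPLITLINE) for v in x])
        y = y + rng.normal(0, 1.5, x.size)
        cands = np.arange(180, 451, 10)
        fit = nv.fit_splitline(x, y, candidates=cands, refine=False)
        for c in cands:
            _, sse_c = hinge_ols_oracle(x, y, c)
            assert fit.sse <= sse_c + 1e-9

    def test_perfectly_linear_data_gives_zero_slope_change(self):
        """A single true line yields equal segment slopes and the smallest
        candidate as tie-broken breakpoint."""
        x = np.repeat(np.array([0.0, 100, 200, 300, 400, 500]), 2)
        y = 5.0 + 0.01 * x
        cands = [150.0, 250.0, 350.0]
        fit = nv.fit_splitline(x, y, candidates=cands, refine=False)
        assert fit.slope_below == pytest.approx(fit.slope_above, abs=1e-10)
        assert fit.breakpoint == 150.0

    def test_slope_difference_shrinks_with_noise(self):
        """Fitting data from a single line, the estimated slope change
        converges to zero as noise vanishes."""
        x = np.repeat(np.linspace(0, 690, 8), 4)
        rng = np.random.default_rng(5)
        diffs = []
        for sd in (2.0, 0.5, 0.01):
            y = 20.0 - 0.005 * x + rng.normal(0, sd, x.size)
            fit = nv.fit_splitline(x, y)
            diffs.append(abs(fit.slope_above - fit.slope_below))
        assert diffs[2] < diffs[0]
        assert diffs[2] < 1e-3

    def test_degenerate_and_unsupported_inputs(self):
        with pytest.raises(nv.DegenerateInputError):
            nv.fit_splitline([1, 1, 1, 1, 1], [1, 2, 3, 4, 5])
        with pytest.raises(nv.InsufficientSupportError):
            nv.fit_splitline([0, 0, 0, 0, 700], [1, 2, 3, 4, 5], candidates=[350.0])
        with pytest.raises(nv.InvalidArgumentError):
            nv.fit_splitline([1, 2, 3], [1, 2, 3])


class TestDecline:
    def test_printed_decline_rate(self, noise_free_milk):
        """The fitted upper slope -0.0235 kg/g is a 2.35 kg/100 g decline."""
        x, y = noise_free_milk
        fit = nv.fit_splitline(x, y)
        assert nv.decline_per_100g(fit) == pytest.approx(2.35, abs=1e-9)

    def test_non_decline_flagged(self):
        fit = nv.SplitLineFit(20.5, 0.0029, 0.0, 350, 0.0, 1.0, 21, 0.5)
        with pytest.warns(nv.ImplausibleValueWarning):
            assert nv.decline_per_100g(fit) is None

    def test_arbitrary_slope(self):
        fit = nv.SplitLineFit(20.5, 0.0029, -0.05, 350, 0.0, 1.0, 21, 0.5)
        assert nv.decline_per_100g(fit) == pytest.approx(5.0)


def test_recovery_at_study_scale_short():
    """Sanity check at study scale (15 cows, default noise): 20 seeds give
    a median breakpoint near 350 and decline near 2.35. The full 200-seed
    check lives with the acceptance suite."""
    bps, decs = [], []
    for seed in range(1, 21):
        recs = nv.simulate_phase1(nv.SimulationConfig(seed=seed))
        fit = nv.fit_splitline(
            [r.urea_g for r in recs], [r.milk.yield_kg for r in recs]
        )
        bps.append(fit.breakpoint)
        decs.append(nv.decline_per_100g(fit))
    assert abs(np.median(bps) - 350) <= 50
    assert abs(np.median(decs) - 2.35) <= 0.4
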