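"""Urine-N regression, mixed-model treatment comparison and the skewness
screen, each checked against an independent oracle."""
import numpy as np
import pandas as pd
import pytest

import npartition as nv

from conftest import TRUE_URINE_LINE


def ols_oracle(x, y):
    """Two-parameter normal equations solved by hand."""
    x = np.asarray(x, float)
    X = np.column_stack([np.ones_like(x), x])
    return np.linalg.solve(X.T @ X, X.T @ np.asarray(y, float))


class TestUrineRegression:
    def test_noise_free_pipeline_recovers_printed_line(self, noise_free_config):
        """Zero-noise phase-2 data through the balance pipeline gives
        slope 0.86, intercept -174.2, R² = 1."""
        bal = nv.balance_table(nv.simulate_phase2(noise_free_config))
        fit = nv.fit_urine_regression(bal)
        a, b = TRUE_URINE_LINE
        assert fit.slope == pytest.approx(b, abs=1e-9)
        assert fit.intercept == pytest.approx(a, abs=1e-6)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)

    def test_constant_response(self):
        df = pd.DataFrame(
            {"n_intake_g": [500.0, 600, 700, 550, 650], "urine_n_est_g": 300.0}
        )
        fit = nv.fit_urine_regression(df)
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        assert fit.r2 == 0.0

    def test_five_points_match_hand_solved_normal_equations(self):
        x = np.array([420.0, 510.0, 565.0, 640.0, 755.0])
        y = np.array([180.0, 260.0, 310.0, 360.0, 475.0])
        df = pd.DataFrame({"n_intake_g": x, "urine_n_est_g": y})
        fit = nv.fit_urine_regression(df)
        a, b = ols_oracle(x, y)
        assert fit.intercept == pytest.approx(a, rel=1e-10)
        assert fit.slope == pytest.approx(b, rel=1e-10)

    def test_zero_intake_variance_rejected(self):
        df = pd.DataFrame({"n_intake_g": [500.0] * 5, "urine_n_est_g": [1.0, 2, 3, 4, 5]})
        with pytest.raises(nv.DegenerateInputError):
            nv.fit_urine_regression(df)

    def test_recovery_at_study_scale_short(self):
        """20 default-noise replicates at 10 cows x 7 d: mean slope and
        intercept near the generating line (full 200-seed check in the
        acceptance suite)."""
        slopes, intercepts = [], []
        for seed in range(1, 21):
            bal = nv.balance_table(nv.simulate_phase2(nv.SimulationConfig(seed=seed)))
            fit = nv.fit_urine_regression(bal)
            slopes.append(fit.slope)
            intercepts.append(fit.intercept)
        assert abs(np.mean(slopes) - 0.86) <= 0.05
        assert abs(np.mean(intercepts) - (-174.2)) <= 25

    def test_r2_decreases_with_noise(self):
        """R² = 1 at zero noise and decreases monotonically along a noise
        grid (averaged over seeds)."""
        grid = [0.0, 10.0, 40.0]
        mean_r2 = []
        for sd in grid:
            r2s = []
            for seed in range(1, 6):
                cfg = nv.SimulationConfig(
                    seed=seed, noise_sd_urine=sd, cow_sd_urine=0.0
                )
                fit = nv.fit_urine_regression(
                    nv.balance_table(nv.simulate_phase2(cfg))
                )
                r2s.append(fit.r2)
            mean_r2.append(np.mean(r2s))
        assert mean_r2[0] == pytest.approx(1.0, abs=1e-9)
        assert mean_r2[0] > mean_r2[1] > mean_r2[2]


def balanced_frame(mean_low, mean_med, n_cows=4, n_days=3, cow_sd=0.0, noise=None):
    rows = []
    rng = np.random.default_rng(0)
    for t, mean in (("low_n", mean_low), ("medium_n", mean_med)):
        for c in range(n_cows):
            cow_eff = rng.normal(0, cow_sd) if cow_sd else 0.0
            for d in range(n_days):
                eps = noise[t][c][d] if noise is not None else 0.0
                rows.append(
                    {
                        "cow_id": f"{t}-{c}",
                        "treatment": t,
                        "value": mean + cow_eff + eps,
                    }
                )
    return pd.DataFrame(rows)


class TestCompareTreatments:
    def test_balanced_zero_noise_lsmeans_are_group_means(self):
        """LS means reproduce the group means exactly: 563 vs 674 g N/d."""
        df = balanced_frame(563.0, 674.0)
        # add within-cow day variation so REML has a residual to estimate
        rng = np.random.default_rng(1)
        df["value"] = df["value"] + np.tile([-1.0, 0.0, 1.0], 8)
        cmp = nv.compare_treatments(df, "value")
        assert cmp.lsmean_low == pytest.approx(563.0, abs=1e-6)
        assert cmp.lsmean_medium == pytest.approx(674.0, abs=1e-6)
        assert cmp.p_value < 1e-6

    def test_identical_groups_null_result(self):
        """Identical data in both groups: LS-mean difference 0, p ~ 1."""
        df = balanced_frame(500.0, 500.0)
        df["value"] = df["value"] + np.tile([-2.0, 1.0, 1.0], 8)
        cmp = nv.compare_treatments(df, "value")
        assert cmp.lsmean_low == pytest.approx(cmp.lsmean_medium, abs=1e-8)
        assert cmp.p_value >= 0.99

    def test_balanced_designs_match_direct_averaging_oracle(self):
        """Mixed-model LS means equal raw treatment means on 50 random
        balanced instances (direct-averaging oracle)."""
        rng = np.random.default_rng(2024)
        for _ in range(50):
            n_cows = int(rng.integers(3, 6))
            n_days = int(rng.integers(2, 5))
            noise = {
                t: rng.normal(0, 5.0, size=(n_cows, n_days))
                for t in ("low_n", "medium_n")
            }
            df = balanced_frame(
                float(rng.uniform(400, 600)),
                float(rng.uniform(500, 800)),
                n_cows=n_cows,
                n_days=n_days,
                cow_sd=10.0,
                noise=noise,
            )
            cmp = nv.compare_treatments(df, "value")
            raw = df.groupby("treatment")["value"].mean()
            assert cmp.lsmean_low == pytest.approx(raw["low_n"], abs=1e-6)
            assert cmp.lsmean_medium == pytest.approx(raw["medium_n"], abs=1e-6)

    def test_single_cow_treatment_rejected(self):
        df = balanced_frame(500.0, 600.0, n_cows=1)
        with pytest.raises(nv.InsufficientReplicationError):
            nv.compare_treatments(df, "value")

    def test_sem_positive_on_noisy_data(self):
        rng = np.random.default_rng(3)
        noise = {t: rng.normal(0, 8.0, size=(5, 4)) for t in ("low_n", "medium_n")}
        df = balanced_frame(560.0, 670.0, n_cows=5, n_days=4, cow_sd=12.0, noise=noise)
        cmp = nv.compare_treatments(df, "value")
        assert cmp.sem > 0
        assert cmp.n_cows == 10
        assert cmp.n_days == 4


class TestNormalityScreen:
    def test_symmetric_sample_has_zero_skew(self):
        vals = [-3.0, -2.0, -1.0, -0.5, 0.5, 1.0, 2.0, 3.0]
        screen = nv.normality_screen(vals)
        assert screen.skewness == pytest.approx(0.0, abs=1e-12)
        assert not screen.flagged

    def test_exponential_like_sample_flagged(self):
        rng = np.random.default_rng(11)
        vals = rng.exponential(1.0, 200)
        screen = nv.normality_screen(vals)
        # independent direct-formula oracle: adjusted Fisher-Pearson g1
        n = vals.size
        m = vals.mean()
        m2 = ((vals - m) ** 2).mean()
        m3 = ((vals - m) ** 3).mean()
        g1 = m3 / m2**1.5
        adj = np.sqrt(n * (n - 1)) / (n - 2) * g1
        assert screen.skewness == pytest.approx(adj, rel=1e-10)
        assert screen.flagged

    def test_small_or_constant_samples_rejected(self):
        with pytest.raises(nv.InvalidArgumentError):
            nv.normality_screen([1.0, 2.0, 3.0])
        with pytest.raises(nv.DegenerateInputError):
            nv.normality_screen([2.0] * 10)
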