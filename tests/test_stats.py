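import numpy as np
import pandas as pd
import pytest

from _oracles import mc_rm_power_oracle, rm_anova_ss_oracle
from photoduet import (ConfigError, PhotoduetError, PowerSpec,
                       anticipatory_index, auc_latency_correlation, cohens_f,
                       dose_response_table, greenhouse_geisser_epsilon,
                       partial_eta_sq, press_latency, rm_anova_oneway,
                       rm_power, rm_sample_size)


class TestPressLatency:
    def test_simple_latency(self):
        assert press_latency(10.0, [12.5, 14.0]) == 2.5

    def test_no_press_incomplete(self):
        assert press_latency(10.0, []) == np.inf
        assert press_latency(10.0, [100.0], next_extension_time=50.0) == np.inf

    def test_press_before_extension_rejected(self):
        with pytest.raises(PhotoduetError):
            press_latency(10.0, [8.0])


class TestAnticipatoryIndex:
    def test_uniform_poking_zero(self):
        entries = np.linspace(0.1, 9.9, 20)  # ~uniform over a 10 s CS
        assert anticipatory_index(entries, 0.0, 10.0) == 0

    def test_last_quintile_only(self):
        entries = [8.1, 8.5, 9.0, 9.9]
        assert anticipatory_index(entries, 0.0, 10.0) == 4

    def test_no_entries_zero(self):
        assert anticipatory_index([], 0.0, 10.0) == 0

    def test_q4_counts_too(self):
        entries = [6.1, 6.5, 7.0]  # all in Q4
        assert anticipatory_index(entries, 0.0, 10.0) == 3


class TestAucLatencyCorrelation:
    def test_perfect_linear_relation(self):
        df = pd.DataFrame({"total_auc": [0.5, 1.0, 1.5, 2.0, 3.0]})
        df["latency_s"] = 2.0 + df["total_auc"]
        r, p, n = auc_latency_correlation(df)
        assert r == pytest.approx(1.0)
        assert n == 5

    def test_too_few_trials_rejected(self):
        df = pd.DataFrame({"total_auc": [1, 2], "latency_s": [3, 4]})
        with pytest.raises(ConfigError):
            auc_latency_correlation(df)

    def test_shuffled_pairing_is_null(self):
        """Permuted latencies: |r| small in the vast majority of seeds."""
        rng = np.random.default_rng(7)
        hits = 0
        for _ in range(100):
            auc = rng.normal(size=200)
            lat = rng.permutation(auc) + rng.normal(size=200)
            r, _, _ = auc_latency_correlation(
                pd.DataFrame({"total_auc": auc, "latency_s": lat}))
            hits += abs(r) < 0.2
        assert hits >= 95


class TestRmAnova:
    def test_identical_columns_f_zero(self):
        data = np.tile(np.arange(5.0)[:, None], (1, 4))
        res = rm_anova_oneway(data)
        assert res.F == 0.0
        assert res.partial_eta_sq == 0.0

    def test_two_conditions_epsilon_one(self):
        rng = np.random.default_rng(0)
        res = rm_anova_oneway(rng.normal(size=(6, 2)))
        assert res.epsilon_gg == 1.0

    def test_sums_of_squares_match_bruteforce(self):
        rng = np.random.default_rng(3)
        data = rng.normal(size=(5, 6))
        res = rm_anova_oneway(data)
        ora = rm_anova_ss_oracle(data)
        assert res.F == pytest.approx(ora["F"], abs=1e-9)

    def test_matches_pingouin(self):
        """Independent cross-check of F, GG epsilon and corrected p."""
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(9)
        data = rng.normal(size=(8, 4)) + np.arange(4) * 0.8
        long = pd.DataFrame(data).reset_index().melt(
            id_vars="index", var_name="cond", value_name="y")
        pg = pingouin.rm_anova(data=long, dv="y", within="cond",
                               subject="index", correction=True)
        res = rm_anova_oneway(data)
        assert res.F == pytest.approx(float(pg["F"].iloc[0]), rel=1e-6)
        assert res.epsilon_gg == pytest.approx(float(pg["eps"].iloc[0]), rel=1e-6)
        assert res.p == pytest.approx(float(pg["p_GG_corr"].iloc[0]), rel=1e-4)

    def test_missing_cells_rejected(self):
        data = np.ones((4, 3))
        data[1, 2] = np.nan
        with pytest.raises(ConfigError, match="mixed-model"):
            rm_anova_oneway(data)

    def test_result_invariant_eta_formula(self):
        rng = np.random.default_rng(5)
        res = rm_anova_oneway(rng.normal(size=(7, 5)) + np.arange(5))
        expected = res.F * res.df_effect / (res.F * res.df_effect + res.df_error)
        assert res.partial_eta_sq == pytest.approx(expected, abs=1e-12)


class TestEffectSizes:
    def test_zero_effect(self):
        assert partial_eta_sq(0.0, 2.0, 10.0) == 0.0
        assert cohens_f(0.0) == 0.0

    def test_cohens_f_half_is_one(self):
        assert cohens_f(0.5) == 1.0

    def test_eta_one_flagged(self):
        with pytest.raises(PhotoduetError):
            cohens_f(1.0)


class TestPower:
    def test_analytic_power_matches_monte_carlo(self):
        """50k-draw noncentral-F simulation agrees within 0.01."""
        spec = dict(f=1.46, m=6, alpha=0.05, rho=-0.068, epsilon=0.3193)
        n = rm_sample_size(PowerSpec(power_target=0.8, **spec))
        analytic = rm_power(spec["f"], n, spec["m"], spec["alpha"],
                            spec["rho"], spec["epsilon"])
        mc = mc_rm_power_oracle(spec["f"], n, spec["m"], spec["alpha"],
                                spec["rho"], spec["epsilon"])
        assert mc == pytest.approx(analytic, abs=0.01)

    def test_minimality_of_returned_n(self):
        spec = PowerSpec(f=0.6, m=4, rho=0.2, epsilon=0.8)
        n = rm_sample_size(spec)
        assert rm_power(0.6, n, 4, 0.05, 0.2, 0.8) >= 0.8
        if n > 2:
            assert rm_power(0.6, n - 1, 4, 0.05, 0.2, 0.8) < 0.8

    def test_huge_effect_floors_at_two(self):
        assert rm_sample_size(PowerSpec(f=100.0, m=3)) == 2

    def test_monotone_in_f_and_power(self):
        ns_f = [rm_sample_size(PowerSpec(f=f, m=4, rho=0.1, epsilon=0.9))
                for f in (0.3, 0.5, 0.8, 1.2)]
        assert all(np.diff(ns_f) <= 0)
        ns_p = [rm_sample_size(PowerSpec(f=0.5, m=4, rho=0.1, epsilon=0.9,
                                         power_target=p))
                for p in (0.5, 0.8, 0.95)]
        assert all(np.diff(ns_p) >= 0)


class TestDoseResponse:
    def _metrics(self, effect=0.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for s in range(4):
            for j, dose in enumerate(["saline", "lo", "hi"]):
                for trial in range(6):
                    rows.append({"subject": f"m{s}", "dose": dose,
                                 "duration_s": 1.0 - effect * j
                                 + rng.normal(0, 0.05)})
        return pd.DataFrame(rows)

    def test_identical_sessions_zero_trend(self):
        df = self._metrics(effect=0.0)
        df["duration_s"] = 1.0
        dr = dose_response_table(df, "duration_s", ["saline", "lo", "hi"])
        assert np.isnan(dr.spearman_rho) or abs(dr.spearman_rho) < 1e-9

    def test_decreasing_effect_negative_trend(self):
        dr = dose_response_table(self._metrics(effect=0.3),
                                 "duration_s", ["saline", "lo", "hi"])
        assert dr.spearman_rho < -0.8
        assert dr.anova is not None
        assert dr.anova.p < 0.05

    def test_single_subject_trend_without_anova(self):
        df = self._metrics(effect=0.3)
        df = df[df["subject"] == "m0"]
        dr = dose_response_table(df, "duration_s", ["saline", "lo", "hi"])
        assert dr.anova is None
        assert dr.spearman_rho < 0

    def test_fewer_than_two_doses_rejected(self):
        with pytest.raises(ConfigError):
            dose_response_table(self._metrics(), "duration_s", ["saline"])
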