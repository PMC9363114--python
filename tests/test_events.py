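import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import dense_dip_oracle
from conftest import make_row
from photoduet import (AnalysisConfig, baseline_sd, detect_dip, detect_peak,
                       filter_trials, opto_onset_latency)


class TestBaselineSd:
    def test_constant_baseline_zero(self, acfg, rel_time):
        assert baseline_sd(rel_time, np.zeros_like(rel_time), acfg) == 0.0

    def test_matches_direct_formula(self, acfg, rel_time):
        rng = np.random.default_rng(0)
        row = rng.normal(size=rel_time.size)
        seg = row[(rel_time >= -acfg.baseline_s) & (rel_time < 0)]
        mean = seg.sum() / seg.size
        direct = np.sqrt(((seg - mean) ** 2).sum() / (seg.size - 1))
        assert baseline_sd(rel_time, row, acfg) == pytest.approx(direct)


class TestDetectDip:
    def test_all_zero_row_unqualified(self, acfg, rel_time):
        dip = detect_dip(rel_time, np.zeros_like(rel_time), acfg)
        assert not dip.qualified
        assert dip.duration_s == 0.0

    def test_piecewise_linear_hand_computed(self, acfg, rel_time):
        """0 at 0.1, -1 at 0.7, 0 at 1.3: amplitude -1, duration 1.2, t_min 0.7."""
        row = make_row(rel_time, [(0.1, 0.0), (0.7, -1.0), (1.3, 0.0)])
        dip = detect_dip(rel_time, row, acfg)
        assert dip.qualified
        assert dip.amplitude_pct == pytest.approx(-1.0)
        assert dip.t_min_s == pytest.approx(0.7)
        assert dip.duration_s == pytest.approx(1.2)

    def test_interpolated_crossing(self, acfg):
        """Samples +0.5 at t=0.0 and -0.5 at t=0.1: crossing at 0.05."""
        dt = 0.1
        rel_time = np.arange(-50, 101) * dt
        row = np.zeros_like(rel_time)
        i0 = np.argmin(np.abs(rel_time))
        row[i0] = 0.5
        row[i0 + 1] = -0.5
        dip = detect_dip(rel_time, row, acfg)
        assert dip.crossing_pre_s == pytest.approx(0.05)

    def test_censored_dip_runs_to_window_end(self, acfg, rel_time):
        row = np.where(rel_time > 0.5, -2.0, 0.0)
        dip = detect_dip(rel_time, row, acfg)
        assert dip.censored
        assert dip.duration_s <= acfg.auc_window_s
        assert dip.rebound_auc == 0.0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.floats(0.1, 50.0))
    def test_positive_scaling_invariance(self, c):
        """Scaling by c > 0 scales amplitude and AUCs by c, duration unchanged."""
        acfg = AnalysisConfig()
        rel_time = np.arange(-50, 101) * 0.1
        row = make_row(rel_time, [(0.2, 0.5), (0.8, -1.5), (1.6, 0.4), (2.4, 0.0)])
        d1 = detect_dip(rel_time, row, acfg)
        d2 = detect_dip(rel_time, c * row, acfg)
        assert d2.amplitude_pct == pytest.approx(c * d1.amplitude_pct, rel=1e-9)
        assert d2.duration_s == pytest.approx(d1.duration_s, rel=1e-9)
        for a, b in ((d1.neg_auc, d2.neg_auc), (d1.rebound_auc, d2.rebound_auc),
                     (d1.total_auc, d2.total_auc)):
            assert b == pytest.approx(c * a, rel=1e-9, abs=1e-12)


class TestAucDecomposition:
    def test_triangle_dip_and_rebound(self, acfg, rel_time):
        """Triangle dip 0->-1->0 over [0,1] then triangle rebound 0->0.5->0
        over [1,2]: neg=-0.5, rebound=+0.25, total=-0.25."""
        row = make_row(rel_time, [(0.0, 0.0), (0.5, -1.0), (1.0, 0.0),
                                  (1.5, 0.5), (2.0, 0.0)])
        dip = detect_dip(rel_time, row, acfg)
        assert dip.neg_auc == pytest.approx(-0.5)
        assert dip.rebound_auc == pytest.approx(0.25)
        assert dip.total_auc == pytest.approx(-0.25)

    def test_initial_peak_counts_only_in_total(self, acfg, rel_time):
        """A positive lobe before the dip contributes to total AUC but to
        neither the negative nor the rebound component."""
        base = make_row(rel_time, [(1.0, 0.0), (1.5, -1.0), (2.0, 0.0),
                                   (2.5, 0.5), (3.0, 0.0)])
        with_peak = base + make_row(rel_time, [(0.0, 0.0), (0.2, 0.8), (0.4, 0.0)])
        d0 = detect_dip(rel_time, base, acfg)
        d1 = detect_dip(rel_time, with_peak, acfg)
        assert d1.neg_auc == pytest.approx(d0.neg_auc)
        assert d1.rebound_auc == pytest.approx(d0.rebound_auc)
        assert d1.total_auc == pytest.approx(d0.total_auc + 0.16)

    def test_decomposition_additivity(self, acfg, rel_time):
        """Splitting the window at the dip's crossings preserves the total
        integral, and the negative component equals the between-crossings
        integral (trapezoid additivity) on random piecewise-linear rows."""
        from _oracles import random_piecewise_linear_rows
        from photoduet.events import _integral, _window
        rows = random_piecewise_linear_rows(rel_time, 50, seed=5)
        checked = 0
        for row in rows:
            dip = detect_dip(rel_time, row, acfg)
            if dip.amplitude_pct >= 0 or dip.censored:
                continue
            t, v = _window(rel_time, row, acfg)
            head = _integral(t, v, t[0], dip.crossing_pre_s)
            mid = _integral(t, v, dip.crossing_pre_s, dip.crossing_post_s)
            tail = _integral(t, v, dip.crossing_post_s, t[-1])
            assert head + mid + tail == pytest.approx(dip.total_auc, abs=1e-9)
            assert mid == pytest.approx(dip.neg_auc, abs=1e-9)
            checked += 1
        assert checked >= 20


class TestDetectPeak:
    def test_zero_row_unqualified(self, acfg, rel_time):
        assert not detect_peak(rel_time, np.zeros_like(rel_time), acfg).qualified

    def test_triangle_peak(self, acfg, rel_time):
        row = make_row(rel_time, [(0.0, 0.0), (0.5, 2.0), (1.0, 0.0)])
        pk = detect_peak(rel_time, row, acfg)
        assert pk.qualified
        assert pk.amplitude_pct == pytest.approx(2.0)
        assert pk.auc == pytest.approx(1.0)
        assert pk.t_max_s == pytest.approx(0.5)

    def test_negative_only_row_unqualified_with_amplitude(self, acfg, rel_time):
        row = make_row(rel_time, [(0.5, 0.0), (1.0, -1.0), (1.5, 0.0)])
        pk = detect_peak(rel_time, row, acfg)
        assert not pk.qualified
        assert pk.amplitude_pct <= 0.0


class TestOracleEquivalence:
    def test_random_rows_match_dense_integrator(self, acfg, rel_time):
        """Dip duration and AUC decomposition match a 1000x-oversampled
        brute-force integrator within 1% on random piecewise-linear rows."""
        from _oracles import random_piecewise_linear_rows
        rows = random_piecewise_linear_rows(rel_time, 100, seed=17)
        for row in rows:
            dip = detect_dip(rel_time, row, acfg)
            ora = dense_dip_oracle(rel_time, row, acfg.auc_window_s,
                                   zero_band=acfg.zero_band_pct)
            dt_fine = 0.1 / 1000
            if dip.amplitude_pct >= -acfg.zero_band_pct:
                assert ora["duration"] == 0.0
                continue
            assert dip.duration_s == pytest.approx(
                ora["duration"], rel=0.01, abs=2 * dt_fine)
            assert dip.total_auc == pytest.approx(ora["total"], rel=0.01, abs=1e-6)
            assert dip.neg_auc == pytest.approx(ora["neg"], rel=0.01, abs=1e-4)
            assert dip.rebound_auc == pytest.approx(ora["rebound"], rel=0.01, abs=1e-4)


class TestOptoOnset:
    def test_step_latency(self, acfg):
        """Step to -3% at t=0.2 with baseline SD 0.1: latency 0.2 s."""
        dt = 0.01
        rel_time = np.arange(-500, 1001) * dt
        rng = np.random.default_rng(1)
        row = np.where(rel_time >= 0.2, -3.0, 0.0)
        row[rel_time < 0] += rng.normal(0, 0.1, size=(rel_time < 0).sum())
        lat = opto_onset_latency(rel_time, row, acfg)
        assert lat == pytest.approx(0.2, abs=dt)

    def test_flat_row_returns_none(self, acfg, rel_time):
        assert opto_onset_latency(rel_time, np.zeros_like(rel_time), acfg) is None

    def test_brief_blip_not_sustained(self, acfg):
        dt = 0.01
        rel_time = np.arange(-500, 1001) * dt
        row = np.zeros_like(rel_time)
        rng = np.random.default_rng(2)
        row[rel_time < 0] = rng.normal(0, 0.1, size=(rel_time < 0).sum())
        i = np.searchsorted(rel_time, 0.5)
        row[i] = -3.0  # single-sample artifact, < 50 ms
        assert opto_onset_latency(rel_time, row, acfg) is None


class TestFilterTrials:
    def test_strictly_greater(self, acfg):
        table = pd.DataFrame({"latency_s": [1.0, 2.0, 3.0], "x": [1, 2, 3]})
        kept = filter_trials(table, acfg)
        assert list(kept["x"]) == [3]

    def test_empty_table(self, acfg):
        table = pd.DataFrame({"latency_s": pd.Series(dtype=float)})
        assert len(filter_trials(table, acfg)) == 0

    def test_identity_when_all_pass(self, acfg):
        table = pd.DataFrame({"latency_s": [2.5, 4.0]})
        assert len(filter_trials(table, acfg)) == 2
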