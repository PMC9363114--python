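"""Per-trial quantification of the ACh dip and DA peak.

All operations act on one baseline-subtracted trial row (from
:class:`~photoduet.preprocess.TrialMatrix`).  Quantification is restricted to
the ``auc_window_s`` seconds after the event.  A dip (peak) qualifies when its
extremum is at least ``dip_sd_k`` (``peak_sd_k``) standard deviations of the
local baseline below (above) zero.  Dip duration runs between the last
zero down-crossing before and the first zero up-crossing after the minimum,
with crossing times located by linear interpolation between samples; a dip
that has not returned to zero by the end of the window keeps the window-end
duration and is flagged censored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import AnalysisConfig

logger = logging.getLogger(__name__)


@dataclass
class DipMetrics:
    amplitude_pct: float       # minimum of the row over (0, auc_window_s]
    duration_s: float
    t_min_s: float
    crossing_pre_s: float
    crossing_post_s: float
    neg_auc: float             # %*s, <= 0
    rebound_auc: float         # %*s, >= 0
    total_auc: float           # %*s, signed, whole AUC window
    qualified: bool
    censored: bool


@dataclass
class PeakMetrics:
    amplitude_pct: float       # maximum of the row over (0, auc_window_s]
    t_max_s: float
    auc: float                 # signed integral over the AUC window
    qualified: bool


def baseline_sd(rel_time: np.ndarray, row: np.ndarray, config: AnalysisConfig) -> float:
    """Sample SD of the [-baseline_s, 0) segment of a trial row."""
    mask = (rel_time >= -config.baseline_s) & (rel_time < 0)
    seg = row[mask]
    if seg.size < 2:
        return 0.0
    return float(np.std(seg, ddof=1))


def _window(rel_time: np.ndarray, row: np.ndarray, config: AnalysisConfig):
    mask = (rel_time >= 0) & (rel_time <= config.auc_window_s + 1e-12)
    return rel_time[mask], row[mask]


def _cross_time(t1: float, v1: float, t2: float, v2: float) -> float:
    """Zero-crossing time on the segment (t1,v1)-(t2,v2) with sign(v1) != sign(v2)."""
    if v1 == 0.0:
        return t1
    if v2 == 0.0:
        return t2
    return t1 + (t2 - t1) * v1 / (v1 - v2)


def _crossings_around_min(t: np.ndarray, v: np.ndarray, i_min: int
                          ) -> tuple[float, float, bool]:
    """Last down-crossing before and first up-crossing after the minimum.

    When the sample on the zero side of a crossing pair is exactly zero (a
    flat baseline run), the true departure point lies somewhere inside that
    sample interval; it is estimated by extrapolating the adjacent signal
    segment back to zero (clamped to the interval) instead of snapping to the
    zero sample, which would systematically widen the dip by up to a sample.
    """
    pre = t[0]
    for j in range(i_min, 0, -1):
        if v[j - 1] >= 0.0 > v[j]:
            if v[j - 1] == 0.0 and j + 1 < v.size and v[j + 1] < v[j]:
                slope = (v[j + 1] - v[j]) / (t[j + 1] - t[j])
                pre = min(max(t[j] - v[j] / slope, t[j - 1]), t[j])
            else:
                pre = _cross_time(t[j - 1], v[j - 1], t[j], v[j])
            break
    censored = True
    post = t[-1]
    for j in range(i_min, v.size - 1):
        if v[j] < 0.0 <= v[j + 1]:
            if v[j + 1] == 0.0 and j >= 1 and v[j - 1] < v[j]:
                slope = (v[j] - v[j - 1]) / (t[j] - t[j - 1])
                post = min(max(t[j] - v[j] / slope, t[j]), t[j + 1])
            else:
                post = _cross_time(t[j], v[j], t[j + 1], v[j + 1])
            censored = False
            break
    return float(pre), float(post), censored


def _integral(t: np.ndarray, v: np.ndarray, lo: float, hi: float) -> float:
    """Trapezoidal integral of the piecewise-linear (t, v) over [lo, hi]."""
    if hi <= lo:
        return 0.0
    inner = (t > lo) & (t < hi)
    tt = np.concatenate([[lo], t[inner], [hi]])
    vv = np.interp(tt, t, v)
    return float(np.trapezoid(vv, tt))


def _integral_pos(t: np.ndarray, v: np.ndarray, lo: float, hi: float) -> float:
    """Integral of the positive part of the piecewise-linear (t, v) over
    [lo, hi], exact: zero crossings are inserted before clipping."""
    if hi <= lo:
        return 0.0
    inner = (t > lo) & (t < hi)
    tt = np.concatenate([[lo], t[inner], [hi]])
    vv = np.interp(tt, t, v)
    sign_change = vv[:-1] * vv[1:] < 0
    if np.any(sign_change):
        extra = [_cross_time(tt[i], vv[i], tt[i + 1], vv[i + 1])
                 for i in np.flatnonzero(sign_change)]
        tt = np.sort(np.concatenate([tt, extra]))
        vv = np.interp(tt, t, v)
        vv[np.isin(tt, extra)] = 0.0
    return float(np.trapezoid(np.maximum(vv, 0.0), tt))


def detect_dip(rel_time: np.ndarray, row: np.ndarray, config: AnalysisConfig) -> DipMetrics:
    """Locate and quantify the post-event dip of one trial row.

    Also fills the AUC decomposition: total (signed, full window), negative
    (between the dip's two crossings) and rebound (positive segment from the
    dip's end crossing to the next down-crossing or the window end).
    """
    t, v = _window(rel_time, row, config)
    sd = baseline_sd(rel_time, row, config)
    post_mask = t > 0
    i_min = int(np.argmin(np.where(post_mask, v, np.inf)))
    amplitude = float(v[i_min])
    # the zero band keeps numerical residue of the preprocessing chain (slow
    # bleach/fit mismatch, ~1e-4 %) from qualifying as a dip or pushing a
    # zero crossing to the window edge
    tol = config.zero_band_pct
    qualified = amplitude <= -max(config.dip_sd_k * sd, tol)
    total = _integral(t, v, t[0], t[-1])

    if amplitude >= -tol:
        return DipMetrics(amplitude, 0.0, float(t[i_min]), np.nan, np.nan,
                          0.0, 0.0, total, False, False)

    w = np.where(np.abs(v) <= tol, 0.0, v)
    pre, post, censored = _crossings_around_min(t, w, i_min)
    duration = post - pre
    neg = min(0.0, _integral(t, v, pre, post))

    rebound = 0.0
    if not censored:
        # positive part up to the next down-crossing (or the window end)
        reb_end = t[-1]
        j_start = int(np.searchsorted(t, post))
        for j in range(j_start, w.size - 1):
            if w[j] > 0.0 >= w[j + 1]:
                reb_end = _cross_time(t[j], w[j], t[j + 1], w[j + 1])
                break
        rebound = _integral_pos(t, v, post, reb_end)

    return DipMetrics(amplitude, float(duration), float(t[i_min]), pre, post,
                      neg, rebound, total, bool(qualified), bool(censored))


def auc_components(rel_time: np.ndarray, row: np.ndarray, dip: DipMetrics,
                   config: AnalysisConfig) -> tuple[float, float, float]:
    """(total, negative, rebound) AUC of a row given its dip decomposition."""
    return dip.total_auc, dip.neg_auc, dip.rebound_auc


def detect_peak(rel_time: np.ndarray, row: np.ndarray, config: AnalysisConfig) -> PeakMetrics:
    """Mirror of :func:`detect_dip` for the DA peak; AUC is the signed window integral."""
    t, v = _window(rel_time, row, config)
    sd = baseline_sd(rel_time, row, config)
    post_mask = t > 0
    i_max = int(np.argmax(np.where(post_mask, v, -np.inf)))
    amplitude = float(v[i_max])
    qualified = amplitude >= max(config.peak_sd_k * sd, config.zero_band_pct)
    auc = _integral(t, v, t[0], t[-1])
    return PeakMetrics(amplitude, float(t[i_max]), auc, bool(qualified))


def opto_onset_latency(rel_time: np.ndarray, row: np.ndarray,
                       config: AnalysisConfig) -> float | None:
    """Latency from light onset to a sustained fall below the dip threshold.

    First time t > 0 at which the row drops below -dip_sd_k * baseline SD and
    stays below for at least ``opto_sustain_s``; None if it never does.
    """
    sd = baseline_sd(rel_time, row, config)
    thr = -config.dip_sd_k * sd
    dt = float(np.median(np.diff(rel_time)))
    n_sustain = max(1, int(np.ceil(config.opto_sustain_s / dt)))
    mask = rel_time > 0
    t, v = rel_time[mask], row[mask]
    below = v < thr
    run = 0
    for j in range(below.size):
        run = run + 1 if below[j] else 0
        if run >= n_sustain:
            return float(t[j - n_sustain + 1])
    return None


def quantify_trials(trials, config: AnalysisConfig, sensor_role: str = "ach"
                    ) -> pd.DataFrame:
    """Per-trial metrics table for a TrialMatrix.

    sensor_role 'ach' emits dip metrics + AUC decomposition; 'da' emits peak
    metrics.  Trial metadata columns are carried through.
    """
    rows = []
    for i in range(trials.n_trials):
        row = trials.values[i]
        rec = {"trial": i}
        if len(trials.meta):
            rec.update(trials.meta.iloc[i].to_dict())
        if sensor_role == "ach":
            dip = detect_dip(trials.rel_time_s, row, config)
            rec.update(amplitude_pct=dip.amplitude_pct, duration_s=dip.duration_s,
                       t_min_s=dip.t_min_s, neg_auc=dip.neg_auc,
                       rebound_auc=dip.rebound_auc, total_auc=dip.total_auc,
                       qualified=dip.qualified, censored=dip.censored)
        else:
            pk = detect_peak(trials.rel_time_s, row, config)
            rec.update(amplitude_pct=pk.amplitude_pct, t_max_s=pk.t_max_s,
                       auc=pk.auc, qualified=pk.qualified)
        rows.append(rec)
    return pd.DataFrame(rows)


def filter_trials(metrics: pd.DataFrame, config: AnalysisConfig,
                  latency_col: str = "latency_s") -> pd.DataFrame:
    """Keep trials with press latency strictly above the configured threshold."""
    if latency_col not in metrics.columns:
        raise KeyError(f"metrics table lacks a {latency_col!r} column")
    kept = metrics[metrics[latency_col] > config.press_latency_filter_s]
    logger.info("filter_trials: kept %d/%d trials (latency > %g s)",
                len(kept), len(metrics), config.press_latency_filter_s)
    return kept.reset_index(drop=True)
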