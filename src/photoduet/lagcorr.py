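"""Lagged Pearson cross-correlation between paired DA and ACh signals.

The ACh series is shifted over a grid of integer-sample lags spanning
[-lag_max_s, +lag_max_s]; at each lag the Pearson r is computed per trial on
the overlapping segment and averaged across trials.  Sign convention:
negative lag means ACh features occur after DA features ("ACh lags DA"), so a
dip trailing the DA peak produces a negative extremum at a negative lag.

The negative extremum is the global minimum of the mean correlation curve;
the positive extremum is the maximum restricted to lags at or below a
configurable bound (default -0.5 s) so it captures the slow rebound
correlation rather than the shoulder of the trough.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .config import AnalysisConfig
from .exceptions import ConfigError, PhotoduetError
from .preprocess import DffTrace, TrialMatrix, n_samples

MIN_OVERLAP = 10


@dataclass
class CorrPeak:
    r: float
    lag_s: float
    variance_explained_pct: float


@dataclass
class LagCorrResult:
    lags_s: np.ndarray
    mean_r: np.ndarray
    n_trials: int
    segment: str = "trial"                 # "trial" or "iti"
    neg_peak: CorrPeak | None = None
    pos_peak: CorrPeak | None = None


def _rowwise_pearson(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson r per row of two equally shaped 2-D arrays; NaN for constant rows."""
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    sx = np.sqrt((xc * xc).sum(axis=1))
    sy = np.sqrt((yc * yc).sum(axis=1))
    denom = sx * sy
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc * yc).sum(axis=1) / denom
    r[denom == 0.0] = np.nan
    return np.clip(r, -1.0, 1.0)


def lag_scan(da_rows: np.ndarray, ach_rows: np.ndarray, dt: float,
             config: AnalysisConfig, segment: str = "trial") -> LagCorrResult:
    """Mean correlation-vs-lag curve over paired trial rows.

    ``da_rows`` and ``ach_rows`` are trials x time arrays on a common grid of
    spacing ``dt`` seconds.  At lag tau = k*dt the correlation pairs
    DA[t] with ACh[t - tau] on the overlap (shorter by |k| samples).
    """
    da_rows = np.atleast_2d(np.asarray(da_rows, dtype=float))
    ach_rows = np.atleast_2d(np.asarray(ach_rows, dtype=float))
    if da_rows.shape != ach_rows.shape:
        raise ConfigError("da_rows and ach_rows must have identical shapes")
    n_time = da_rows.shape[1]
    max_k = n_samples(config.lag_max_s, dt)
    if n_time - max_k < MIN_OVERLAP:
        raise ConfigError(
            f"overlap at max lag is {n_time - max_k} samples (<{MIN_OVERLAP}); "
            "reduce lag_max_s or use longer segments")
    lags_k = np.arange(-max_k, max_k + 1)
    mean_r = np.empty(lags_k.size)
    for idx, k in enumerate(lags_k):
        if k < 0:
            d, a = da_rows[:, : n_time + k], ach_rows[:, -k:]
        elif k > 0:
            d, a = da_rows[:, k:], ach_rows[:, : n_time - k]
        else:
            d, a = da_rows, ach_rows
        r = _rowwise_pearson(d, a)
        mean_r[idx] = np.nan if np.all(np.isnan(r)) else np.nanmean(r)
    return LagCorrResult(lags_s=lags_k * dt, mean_r=mean_r,
                         n_trials=da_rows.shape[0], segment=segment)


def find_extrema(result: LagCorrResult, config: AnalysisConfig) -> LagCorrResult:
    """Fill the negative (global-minimum) and positive (bounded-maximum) peaks.

    Ties are broken toward the lag of smaller magnitude.
    """
    lags, r = result.lags_s, result.mean_r
    order = np.lexsort((np.abs(lags), r))
    i_neg = order[0]
    result.neg_peak = CorrPeak(float(r[i_neg]), float(lags[i_neg]),
                               variance_explained(r[i_neg]))
    sel = lags <= config.pos_peak_lag_bound_s + 1e-12
    if not np.any(sel):
        raise ConfigError("no lags at or below pos_peak_lag_bound_s; widen lag_max_s")
    sub_l, sub_r = lags[sel], r[sel]
    order = np.lexsort((np.abs(sub_l), -sub_r))
    i_pos = order[0]
    result.pos_peak = CorrPeak(float(sub_r[i_pos]), float(sub_l[i_pos]),
                               variance_explained(sub_r[i_pos]))
    return result


def lag_scan_trials(da: TrialMatrix, ach: TrialMatrix,
                    config: AnalysisConfig) -> LagCorrResult:
    """Lag scan over paired event-aligned trial matrices, extrema filled."""
    if da.values.shape != ach.values.shape:
        raise ConfigError("paired trial matrices must have identical shapes")
    res = lag_scan(da.values, ach.values, da.dt, config, segment="trial")
    return find_extrema(res, config)


def variance_explained(r: float) -> float:
    """Percent of variance explained by a correlation: r**2 x 100."""
    if abs(r) > 1.0:
        raise PhotoduetError(f"|r| = {abs(r):g} exceeds 1")
    return float(r * r * 100.0)


def fisher_z(r: float) -> float:
    """Fisher transformation z = arctanh(r); infinite at |r| = 1 (warned)."""
    if abs(r) > 1.0:
        raise PhotoduetError(f"|r| = {abs(r):g} exceeds 1")
    if abs(r) == 1.0:
        warnings.warn("|r| = 1 gives an infinite Fisher z", stacklevel=2)
        return float(np.inf if r > 0 else -np.inf)
    return float(np.arctanh(r))


def compare_correlations(r1: float, n1: int, r2: float, n2: int) -> tuple[float, float]:
    """Two-sample z-test for independent Pearson correlations.

    z = (z1 - z2) / sqrt(1/(n1-3) + 1/(n2-3)), two-sided normal p.
    """
    if min(n1, n2) < 4:
        raise ConfigError("need n >= 4 per sample to compare correlations")
    z1, z2 = fisher_z(r1), fisher_z(r2)
    se = np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    z = (z1 - z2) / se
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def iti_segments(da: DffTrace, ach: DffTrace, event_times: np.ndarray,
                 config: AnalysisConfig) -> tuple[np.ndarray, np.ndarray]:
    """Paired DA/ACh inter-trial segments, chunked to fixed-length pieces.

    Samples inside any [-window_pre_s, +window_post_s] peri-event window are
    excluded; the remaining stretches are cut into ``iti_chunk_s`` chunks
    (partial chunks dropped).  Returns (da_chunks, ach_chunks) arrays of shape
    n_chunks x chunk_samples; both empty if no ITI stretch is long enough.
    """
    t = da.time_s
    keep = np.ones(t.size, dtype=bool)
    for ev in np.asarray(event_times, dtype=float):
        keep &= ~((t >= ev - config.window_pre_s) & (t <= ev + config.window_post_s))
    dt = float(np.median(np.diff(t)))
    chunk_n = n_samples(config.iti_chunk_s, dt)
    da_chunks, ach_chunks = [], []
    # split the kept samples into contiguous runs, then into fixed chunks
    idx = np.flatnonzero(keep)
    if idx.size:
        breaks = np.flatnonzero(np.diff(idx) > 1)
        for run in np.split(idx, breaks + 1):
            for s in range(0, run.size - chunk_n + 1, chunk_n):
                sel = run[s: s + chunk_n]
                da_chunks.append(da.dff_pct[sel])
                ach_chunks.append(ach.dff_pct[sel])
    if not da_chunks:
        return (np.empty((0, chunk_n)), np.empty((0, chunk_n)))
    return np.vstack(da_chunks), np.vstack(ach_chunks)


def lag_scan_iti(da: DffTrace, ach: DffTrace, event_times: np.ndarray,
                 config: AnalysisConfig) -> LagCorrResult:
    """ITI lag correlation: chunked segments treated as trials, extrema filled."""
    da_c, ach_c = iti_segments(da, ach, event_times, config)
    if da_c.shape[0] == 0:
        dt = float(np.median(np.diff(da.time_s)))
        max_k = n_samples(config.lag_max_s, dt)
        lags = np.arange(-max_k, max_k + 1) * dt
        return LagCorrResult(lags_s=lags, mean_r=np.full(lags.size, np.nan),
                             n_trials=0, segment="iti")
    dt = float(np.median(np.diff(da.time_s)))
    res = lag_scan(da_c, ach_c, dt, config, segment="iti")
    return find_extrema(res, config)
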