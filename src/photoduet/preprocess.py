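"""Raw dual-wavelength traces -> baseline-subtracted, event-aligned dF/F.

Processing order per sensor: block-mean downsampling of both wavelengths,
least-squares fit of the 405 nm isosbestic channel to the 465 nm signal
channel (the fitted trace is F0), dF/F = (F - F0)/F0 x 100, then extraction
of peri-event windows with per-trial local-baseline subtraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .exceptions import ConfigError, DegenerateFitError, PhotoduetError
from .session import SessionRecord

logger = logging.getLogger(__name__)


@dataclass
class DffTrace:
    """Full-session dF/F (%) for one sensor, with isosbestic-fit diagnostics."""

    time_s: np.ndarray
    dff_pct: np.ndarray
    sensor: str
    slope: float      # a of F0 = a*F405 + b
    intercept: float  # b


@dataclass
class TrialMatrix:
    """Event-aligned, local-baseline-subtracted dF/F rows (trials x time)."""

    rel_time_s: np.ndarray
    values: np.ndarray
    sensor: str
    meta: pd.DataFrame = field(default_factory=pd.DataFrame)  # one row per kept trial
    n_dropped: int = 0

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def dt(self) -> float:
        return float(self.rel_time_s[1] - self.rel_time_s[0])


def n_samples(duration_s: float, dt: float) -> int:
    """Samples spanning a duration on a grid of spacing dt.

    The ratio is quantized before rounding so that half-sample boundaries
    (e.g. 5 s at dt = 0.08 s) resolve identically across sessions instead of
    flipping with floating-point noise in dt.
    """
    return int(np.floor(round(duration_s / dt, 6) + 0.5))


def downsample(trace: np.ndarray, factor: int) -> np.ndarray:
    """Decimate by a non-overlapping moving-window (block) mean.

    Output element i is the mean of input[i*factor : (i+1)*factor]; a trailing
    partial block is dropped, so the output length is floor(len/factor).
    """
    trace = np.asarray(trace, dtype=float)
    if factor < 1 or int(factor) != factor:
        raise ConfigError("downsample factor must be a positive integer")
    factor = int(factor)
    if trace.size < factor:
        raise ConfigError(f"factor {factor} exceeds trace length {trace.size}")
    m = trace.size // factor
    return trace[: m * factor].reshape(m, factor).mean(axis=1)


def fit_isosbestic(f405: np.ndarray, f465: np.ndarray) -> tuple[float, float, np.ndarray]:
    """Least-squares fit F465 ~ a*F405 + b; returns (a, b, F0 = a*F405 + b)."""
    f405 = np.asarray(f405, dtype=float)
    f465 = np.asarray(f465, dtype=float)
    if f405.shape != f465.shape or f405.size < 2:
        raise ConfigError("f405/f465 must be equal-length vectors of length >= 2")
    if np.ptp(f405) == 0.0:
        raise DegenerateFitError("405 nm trace is constant; isosbestic fit is degenerate")
    a, b = np.polyfit(f405, f465, 1)
    return float(a), float(b), a * f405 + b


def compute_dff(f465: np.ndarray, f0: np.ndarray) -> np.ndarray:
    """dF/F in percent: (F - F0)/F0 x 100."""
    f465 = np.asarray(f465, dtype=float)
    f0 = np.asarray(f0, dtype=float)
    if np.any(f0 <= 0):
        bad = int(np.argmax(f0 <= 0))
        raise PhotoduetError(
            f"fitted F0 non-positive at sample {bad} (value {f0[bad]:g}); "
            "check the isosbestic fit diagnostics")
    return (f465 - f0) / f0 * 100.0


def preprocess_sensor(record: SessionRecord, sensor: str,
                      config: AnalysisConfig) -> DffTrace:
    """Downsample both wavelengths of one sensor and compute dF/F."""
    f465 = downsample(record.channels[(sensor, 465)], config.downsample_factor)
    f405 = downsample(record.channels[(sensor, 405)], config.downsample_factor)
    time = downsample(record.time_s, config.downsample_factor)
    a, b, f0 = fit_isosbestic(f405, f465)
    dff = compute_dff(f465, f0)
    return DffTrace(time_s=time, dff_pct=dff, sensor=sensor, slope=a, intercept=b)


def align_trials(dff: DffTrace, event_times: np.ndarray, config: AnalysisConfig,
                 trial_meta: pd.DataFrame | None = None) -> TrialMatrix:
    """Extract peri-event windows and subtract each trial's local baseline.

    Each event becomes one row spanning [-window_pre_s, +window_post_s]
    (nearest-sample alignment, rel_time 0 at the event sample); the mean of
    the [-baseline_s, 0) segment is subtracted from the row.  Events whose
    window does not fit inside the recording are dropped and counted.
    """
    t = dff.time_s
    dt = float(np.median(np.diff(t)))
    n_pre = n_samples(config.window_pre_s, dt)
    n_post = n_samples(config.window_post_s, dt)
    rel_time = np.arange(-n_pre, n_post + 1) * dt

    rows, kept_idx = [], []
    event_times = np.asarray(event_times, dtype=float)
    for k, ev in enumerate(event_times):
        i0 = int(np.argmin(np.abs(t - ev)))
        lo, hi = i0 - n_pre, i0 + n_post + 1
        if lo < 0 or hi > t.size:
            continue
        row = dff.dff_pct[lo:hi].copy()
        base = row[:n_pre][rel_time[:n_pre] >= -config.baseline_s]
        row -= base.mean()
        rows.append(row)
        kept_idx.append(k)

    n_dropped = event_times.size - len(rows)
    if n_dropped:
        logger.info("align_trials: dropped %d truncated trial(s)", n_dropped)
    values = np.vstack(rows) if rows else np.empty((0, rel_time.size))
    if trial_meta is not None:
        meta = trial_meta.iloc[kept_idx].reset_index(drop=True)
    else:
        meta = pd.DataFrame({"event_time_s": event_times[kept_idx]})
    return TrialMatrix(rel_time_s=rel_time, values=values, sensor=dff.sensor,
                       meta=meta, n_dropped=n_dropped)


def align_session(record: SessionRecord, config: AnalysisConfig,
                  event_label: str = "lever_extension",
                  trial_meta: pd.DataFrame | None = None
                  ) -> dict[str, TrialMatrix]:
    """Preprocess both sensors of a session and align to one event type."""
    events = record.event_times(event_label)
    out = {}
    for sensor in ("ACh", "DA"):
        trace = preprocess_sensor(record, sensor, config)
        out[sensor] = align_trials(trace, events, config, trial_meta=trial_meta)
    return out
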