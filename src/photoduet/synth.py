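"""Seeded generator of synthetic dual-sensor photometry sessions.

Emulates the statistical structure the analysis chain assumes: a fast dopamine
transient at each lever extension; a multiphasic acetylcholine response
(optional initial peak, a dip whose minimum trails the DA peak, a later
rebound); dose-dependent shortening of the dip and enhancement of the rebound;
genotype-dependent decoupling; shared motion artifacts on the 405/465
channels; slow photobleaching; spontaneous coupled transients during the ITI;
and press latencies coupled to the trial's total ACh AUC.

Event-locked kernels are half-sine bumps: compact support makes the
configured dip duration exactly the zero-crossing-to-zero-crossing duration,
even symmetry makes the configured peak-to-peak lags exactly the
cross-correlation extremum lags, and the non-zero edge slope keeps
crossing-time estimates stable under sample noise — i.e. the generator's
parameters are the quantities the pipeline is supposed to recover.  The
rebound bump starts exactly at the dip's end crossing (its width is derived
from the configured rebound lag), mimicking the positive component that
immediately follows the ACh decrease in vivo.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import DoseEffect, SimConfig
from .exceptions import ConfigError
from .session import SessionRecord

# raw-fluorescence baselines (arbitrary detector units) per channel
BASELINE_F = {("ACh", 465): 100.0, ("ACh", 405): 80.0,
              ("DA", 465): 120.0, ("DA", 405): 90.0}

GROUND_TRUTH_COLUMNS = [
    "trial", "event_time_s", "true_dip_amp", "true_dip_dur", "true_da_amp",
    "true_rebound_amp", "true_total_auc", "true_lag_s", "latency_s", "completed",
]


BUMP_AREA = 2.0 / np.pi  # integral of a unit half-sine bump of unit width


def _add_bump(signal: np.ndarray, t: np.ndarray, center: float, width: float,
              amp: float) -> None:
    """Add a half-sine bump amp*cos(pi*(t-c)/w) on |t-c| <= w/2 (area 2/pi*amp*w)."""
    if amp == 0.0 or width <= 0.0:
        return
    fs = 1.0 / (t[1] - t[0])
    i0 = max(0, int(np.ceil((center - width / 2 - t[0]) * fs)))
    i1 = min(t.size, int(np.floor((center + width / 2 - t[0]) * fs)) + 1)
    if i1 <= i0:
        return
    tt = t[i0:i1]
    signal[i0:i1] += amp * np.cos(np.pi * (tt - center) / width)


def _rebound_width(cfg: SimConfig, dip_w: float) -> float:
    """Width placing the rebound flush against the dip end with its peak at
    |rebound_lag_s| after the DA peak."""
    w = 2.0 * (-cfg.rebound_lag_s + cfg.da_ach_lag_s - dip_w / 2.0)
    if w <= 0:
        raise ConfigError(
            "rebound_lag_s must exceed da_ach_lag_s + dip half-width in magnitude")
    return w


def _truncated_exponential(rng: np.random.Generator, n: int, scale: float,
                           lo: float, hi: float) -> np.ndarray:
    """Exponential(scale) conditioned on [lo, hi], by inverse CDF."""
    flo = 1.0 - np.exp(-lo / scale)
    fhi = 1.0 - np.exp(-hi / scale)
    u = rng.uniform(flo, fhi, size=n)
    return -scale * np.log1p(-u)


def _opto_kernel(signal: np.ndarray, t: np.ndarray, onset: float, cfg: SimConfig) -> float:
    """Add the optogenetic-inhibition kernel; return its signed area (%*s).

    Square dip of -opto_amp_pct for opto_pulse_s, then a linear ramp back to
    zero over 1 s (short) or 3 s (long); the long mode adds a rebound
    overshoot after the ramp.
    """
    amp = cfg.opto_amp_pct
    ramp_s = 1.0 if cfg.opto_mode == "short" else 3.0
    fs = 1.0 / (t[1] - t[0])
    area = -amp * cfg.opto_pulse_s - amp * ramp_s / 2.0

    i0 = max(0, int(np.ceil((onset - t[0]) * fs)))
    i1 = min(t.size, int(np.floor((onset + cfg.opto_pulse_s - t[0]) * fs)) + 1)
    signal[i0:i1] += -amp
    r0 = i1
    r1 = min(t.size, int(np.floor((onset + cfg.opto_pulse_s + ramp_s - t[0]) * fs)) + 1)
    if r1 > r0:
        tt = t[r0:r1] - (onset + cfg.opto_pulse_s)
        signal[r0:r1] += -amp * (1.0 - tt / ramp_s)
    if cfg.opto_mode == "long":
        reb_w = 1.0
        _add_bump(signal, t, onset + cfg.opto_pulse_s + ramp_s + reb_w / 2.0,
                  reb_w, cfg.ach_rebound_amp_pct)
        area += BUMP_AREA * cfg.ach_rebound_amp_pct * reb_w
    return area


def generate_session(config: SimConfig) -> tuple[SessionRecord, pd.DataFrame]:
    """Generate one session plus its per-trial ground truth.

    Returns
    -------
    record : SessionRecord
        Four raw-fluorescence channels, behavioural/opto events, metadata.
    truth : pandas.DataFrame
        One row per trial with true event time, dip amplitude/duration, DA
        amplitude, rebound amplitude, total AUC, DA->ACh lag, press latency.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    eff = DoseEffect(*cfg.dose_effect[cfg.dose])
    ko_scale = 0.5 if cfg.genotype == "ko" else 1.0

    itis = _truncated_exponential(rng, cfg.n_trials - 1, cfg.iti_mean_s,
                                  cfg.iti_min_s, cfg.iti_max_s)
    event_times = cfg.lead_in_s + np.concatenate([[0.0], np.cumsum(itis)])
    duration = event_times[-1] + cfg.tail_s
    fs = cfg.sampling_rate_hz
    n = int(round(duration * fs))
    t = np.arange(n) / fs

    s_ach = np.zeros(n)   # true dF/F (%) of each sensor
    s_da = np.zeros(n)

    # per-trial amplitude jitter (multiplicative, clipped to stay positive)
    jit = np.clip(rng.normal(1.0, cfg.amp_jitter_cv, size=(cfg.n_trials, 3)), 0.1, None)

    dip_w = cfg.ach_dip_duration_s * eff.dip_duration_mult
    reb_w = _rebound_width(cfg, dip_w)
    truth_rows = []
    for k, t_ev in enumerate(event_times):
        da_amp = cfg.da_peak_amp_pct * eff.da_amp_mult * jit[k, 0]
        dip_amp = cfg.ach_dip_amp_pct * ko_scale * jit[k, 1]
        reb_amp = cfg.ach_rebound_amp_pct * eff.rebound_mult * ko_scale * jit[k, 2]
        peak_amp = cfg.ach_initial_peak_amp_pct * jit[k, 2]
        c_da = t_ev + cfg.da_onset_s + cfg.da_width_s / 2.0

        total_auc = 0.0
        if not cfg.sensor_blocked:
            _add_bump(s_da, t, c_da, cfg.da_width_s, da_amp)
            if cfg.opto_mode == "off":
                _add_bump(s_ach, t, c_da - cfg.da_ach_lag_s, dip_w, dip_amp)
                _add_bump(s_ach, t, c_da - cfg.rebound_lag_s, reb_w, reb_amp)
                _add_bump(s_ach, t, t_ev + cfg.da_onset_s + cfg.ach_initial_peak_width_s / 2.0,
                          cfg.ach_initial_peak_width_s, peak_amp)
                total_auc = BUMP_AREA * (peak_amp * cfg.ach_initial_peak_width_s
                                         + dip_amp * dip_w
                                         + reb_amp * reb_w)
            else:
                total_auc = _opto_kernel(s_ach, t, t_ev + cfg.opto_onset_delay_s, cfg)

        lat_mean = cfg.latency_base_s + cfg.latency_coupling_slope * total_auc
        latency = max(0.1, rng.normal(lat_mean, cfg.latency_noise_sd_s))
        next_ev = event_times[k + 1] if k + 1 < cfg.n_trials else duration
        completed = bool(t_ev + latency + 1.0 < next_ev)
        truth_rows.append((k, t_ev,
                           dip_amp if (cfg.opto_mode == "off" and not cfg.sensor_blocked) else 0.0,
                           dip_w if (cfg.opto_mode == "off" and not cfg.sensor_blocked) else 0.0,
                           da_amp if not cfg.sensor_blocked else 0.0,
                           reb_amp if (cfg.opto_mode == "off" and not cfg.sensor_blocked) else 0.0,
                           total_auc, cfg.da_ach_lag_s,
                           latency if completed else np.inf, completed))

    # spontaneous coupled transients during the ITI, clear of trial windows
    if cfg.spont_rate_hz > 0 and not cfg.sensor_blocked and cfg.opto_mode == "off":
        n_spont = rng.poisson(cfg.spont_rate_hz * duration)
        cand = np.sort(rng.uniform(0.0, duration, size=n_spont))
        for u in cand:
            d = u - event_times
            if np.any((d > -7.0) & (d < 12.0)):
                continue
            sc = cfg.spont_scale * np.clip(rng.normal(1.0, cfg.amp_jitter_cv), 0.1, None)
            c_da = u + cfg.da_width_s / 2.0
            _add_bump(s_da, t, c_da, cfg.da_width_s, cfg.da_peak_amp_pct * sc)
            _add_bump(s_ach, t, c_da - cfg.da_ach_lag_s, cfg.ach_dip_duration_s,
                      cfg.ach_dip_amp_pct * ko_scale * sc)
            _add_bump(s_ach, t, c_da - cfg.rebound_lag_s,
                      _rebound_width(cfg, cfg.ach_dip_duration_s),
                      cfg.ach_rebound_amp_pct * ko_scale * sc)

    # shared motion artifact (%), identical fractional contribution to 405/465
    motion = np.zeros(n)
    if cfg.motion_amp_pct > 0 and cfg.motion_rate_hz > 0:
        n_bumps = rng.poisson(cfg.motion_rate_hz * duration)
        times = rng.uniform(0.0, duration, size=n_bumps)
        amps = (cfg.motion_amp_pct * rng.uniform(0.5, 1.5, size=n_bumps)
                * rng.choice([-1.0, 1.0], size=n_bumps))
        for c, a in zip(times, amps):
            _add_bump(motion, t, c, cfg.motion_width_s, a)

    bleach = np.exp(-t / cfg.bleach_tau_s)
    channels = {}
    for sensor, sig in (("ACh", s_ach), ("DA", s_da)):
        for wl in (465, 405):
            base = BASELINE_F[(sensor, wl)]
            frac = motion + (sig if wl == 465 else 0.0)
            trace = base * bleach * (1.0 + frac / 100.0)
            if cfg.noise_sd_pct > 0:
                trace = trace + base * (cfg.noise_sd_pct / 100.0) * rng.standard_normal(n)
            channels[(sensor, wl)] = trace

    truth = pd.DataFrame(truth_rows, columns=GROUND_TRUTH_COLUMNS)

    ev_rows = [("lever_extension", te) for te in event_times]
    if cfg.opto_mode != "off":
        for te in event_times:
            ev_rows.append(("light_on", te + cfg.opto_onset_delay_s))
            ev_rows.append(("light_off", te + cfg.opto_onset_delay_s + cfg.opto_pulse_s))
    for row in truth.itertuples():
        if row.completed:
            press = row.event_time_s + row.latency_s
            if press < duration:
                ev_rows.append(("lever_press", press))
                ev_rows.append(("reward", press))
            if press + 0.5 < duration:
                ev_rows.append(("head_entry", press + 0.5))
    events = pd.DataFrame(sorted(ev_rows, key=lambda r: r[1]),
                          columns=["label", "time_s"])

    meta = {"subject": cfg.meta_subject, "date": "1970-01-01", "dose": cfg.dose,
            "genotype": cfg.genotype, "task": "crf", "seed": int(cfg.seed),
            "sampling_rate_hz": float(fs), "opto_mode": cfg.opto_mode}
    record = SessionRecord(time_s=t, channels=channels, events=events, meta=meta)
    return record.validate(), truth


def generate_dose_series(base: SimConfig, doses: list[str]
                         ) -> list[tuple[SessionRecord, pd.DataFrame]]:
    """One session per dose label, sharing the base seed.

    Ground-truth dip durations are non-increasing and rebound amplitudes
    non-decreasing along the given dose order, provided the dose_effect map is
    monotone in that order (the default map is).
    """
    for d in doses:
        if d not in base.dose_effect:
            raise ConfigError(f"dose {d!r} missing from dose_effect map")
    return [generate_session(base.replace(dose=d)) for d in doses]


def write_ground_truth(truth: pd.DataFrame, path) -> None:
    """Sidecar CSV of the per-trial ground truth."""
    truth.to_csv(path, index=False)
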