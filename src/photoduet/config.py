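"""Analysis and simulation configuration objects.

`AnalysisConfig` collects every tunable of the trace-processing chain
(downsampling, peri-event window, baseline, AUC window, detection thresholds,
lag-scan bounds).  `SimConfig` parameterises the synthetic dual-sensor session
generator.  Both round-trip through plain dicts so they can be loaded from
YAML/JSON files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import yaml

from .exceptions import ConfigError

GENOTYPES = ("control", "ko")
OPTO_MODES = ("off", "short", "long")


@dataclass
class AnalysisConfig:
    """Tunables of the dF/F -> trial-metrics chain.

    Defaults mirror common fiber-photometry practice: decimate by 10 with a
    block mean, a 15 s peri-event window split [-5 s, +10 s] around the event,
    a 5 s local baseline, quantification restricted to the 5 s after the
    event, and a 2-SD threshold for dip/peak qualification.
    """

    downsample_factor: int = 10
    window_pre_s: float = 5.0
    window_post_s: float = 10.0
    baseline_s: float = 5.0
    auc_window_s: float = 5.0
    dip_sd_k: float = 2.0
    peak_sd_k: float = 2.0
    lag_max_s: float = 3.0
    press_latency_filter_s: float = 2.0
    pos_peak_lag_bound_s: float = -0.5
    iti_chunk_s: float = 10.0
    opto_sustain_s: float = 0.05
    zero_band_pct: float = 1e-3   # |dF/F| below this counts as zero for crossings

    def __post_init__(self) -> None:
        if self.downsample_factor < 1:
            raise ConfigError("downsample_factor must be a positive integer")
        for name in ("window_pre_s", "window_post_s", "baseline_s",
                     "auc_window_s", "dip_sd_k", "peak_sd_k", "lag_max_s"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.baseline_s > self.window_pre_s:
            raise ConfigError("baseline_s must not exceed window_pre_s")
        if self.auc_window_s > self.window_post_s:
            raise ConfigError("auc_window_s must not exceed window_post_s")
        if self.pos_peak_lag_bound_s >= 0:
            raise ConfigError("pos_peak_lag_bound_s must be negative")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown analysis-config keys: {sorted(unknown)}")
        return cls(**d)


class DoseEffect(NamedTuple):
    """Multiplicative effect of one drug dose on the event-locked kernels."""

    dip_duration_mult: float  # in (0, 1]: antagonist shortens the dip
    rebound_mult: float       # >= 1: antagonist enhances the rebound
    da_amp_mult: float = 1.0  # >= 1: antagonist disinhibits DA release


def default_dose_effects() -> dict[str, DoseEffect]:
    """Six-level eticlopride-like series (mg/kg labels), saline first."""
    return {
        "saline": DoseEffect(1.00, 1.0, 1.00),
        "0.1":    DoseEffect(0.90, 1.2, 1.05),
        "0.25":   DoseEffect(0.75, 1.5, 1.10),
        "1.0":    DoseEffect(0.60, 1.8, 1.15),
        "2.5":    DoseEffect(0.50, 2.1, 1.20),
        "5.0":    DoseEffect(0.40, 2.5, 1.25),
    }


@dataclass
class SimConfig:
    """Ground-truth parameters of one synthetic dual-sensor session.

    Event-locked kernels are half-sine bumps (compact support, symmetric),
    so configured amplitudes, durations and peak-to-peak lags are exactly the
    quantities the analysis chain estimates.  Amplitudes are in dF/F percent;
    times in seconds.
    """

    sampling_rate_hz: float = 1000.0
    n_trials: int = 20
    iti_mean_s: float = 40.0
    iti_min_s: float = 20.0
    iti_max_s: float = 80.0
    lead_in_s: float = 20.0
    tail_s: float = 15.0

    # dopamine transient
    da_peak_amp_pct: float = 5.0
    da_width_s: float = 0.8
    da_onset_s: float = 0.1

    # acetylcholine multiphasic response
    ach_initial_peak_amp_pct: float = 0.0   # 0 = "no initial peak" phenotype
    ach_initial_peak_width_s: float = 0.4
    ach_dip_amp_pct: float = -3.0
    ach_dip_duration_s: float = 1.0
    ach_rebound_amp_pct: float = 1.0
    da_ach_lag_s: float = -0.18   # dip minimum trails the DA peak by |lag|
    rebound_lag_s: float = -1.5   # rebound peak trails the DA peak by |lag|

    # condition structure
    dose: str = "saline"
    dose_effect: dict[str, DoseEffect] = field(default_factory=default_dose_effects)
    genotype: str = "control"     # "ko" halves the DA-coupled ACh components
    sensor_blocked: bool = False  # scopolamine mode: event-locked kernels zeroed
    opto_mode: str = "off"        # "short"/"long": square dip + ramp at each event
    opto_amp_pct: float = 1.5
    opto_pulse_s: float = 0.5
    opto_onset_delay_s: float = 0.2   # ACh fall onset after light, ~200 ms

    # behaviour coupling
    latency_base_s: float = 3.0
    latency_coupling_slope: float = 1.0   # s per (%*s) of trial total AUC
    latency_noise_sd_s: float = 0.5
    amp_jitter_cv: float = 0.2            # trial-to-trial kernel amplitude CV

    # nuisance structure
    motion_amp_pct: float = 1.0
    motion_rate_hz: float = 0.1
    motion_width_s: float = 0.3
    bleach_tau_s: float = 2000.0
    noise_sd_pct: float = 0.3
    spont_rate_hz: float = 0.1    # spontaneous coupled transients during the ITI
    spont_scale: float = 0.5      # their amplitude relative to cue-evoked ones

    seed: int = 0
    meta_subject: str = "sim"

    def __post_init__(self) -> None:
        if self.sampling_rate_hz <= 0:
            raise ConfigError("sampling_rate_hz must be positive")
        if self.n_trials < 1:
            raise ConfigError("n_trials must be >= 1")
        if self.ach_dip_amp_pct >= 0:
            raise ConfigError("ach_dip_amp_pct must be negative (it is a dip)")
        if self.ach_dip_duration_s <= 0:
            raise ConfigError("ach_dip_duration_s must be positive")
        if self.da_ach_lag_s >= 0 or self.rebound_lag_s >= 0:
            raise ConfigError("lags are negative: ACh features trail the DA peak")
        if self.genotype not in GENOTYPES:
            raise ConfigError(f"genotype must be one of {GENOTYPES}")
        if self.opto_mode not in OPTO_MODES:
            raise ConfigError(f"opto_mode must be one of {OPTO_MODES}")
        if self.dose not in self.dose_effect:
            raise ConfigError(f"dose {self.dose!r} missing from dose_effect map")
        if not (0 < self.iti_min_s <= self.iti_max_s):
            raise ConfigError("require 0 < iti_min_s <= iti_max_s")
        for key, eff in self.dose_effect.items():
            eff = DoseEffect(*eff)
            if not (0 < eff.dip_duration_mult <= 1):
                raise ConfigError(f"dip_duration_mult for dose {key!r} must be in (0, 1]")
            if eff.rebound_mult < 1 or eff.da_amp_mult < 1:
                raise ConfigError(f"rebound/da multipliers for dose {key!r} must be >= 1")

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["dose_effect"] = {k: list(v) for k, v in self.dose_effect.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "dose_effect" in d:
            d["dose_effect"] = {k: DoseEffect(*v) for k, v in d["dose_effect"].items()}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown sim-config keys: {sorted(unknown)}")
        return cls(**d)


def load_config(path: str | Path, kind: str = "analysis"):
    """Load an AnalysisConfig ('analysis') or SimConfig ('sim') from YAML/JSON."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if data is None:
        data = {}
    if kind == "analysis":
        return AnalysisConfig.from_dict(data)
    if kind == "sim":
        return SimConfig.from_dict(data)
    raise ConfigError(f"unknown config kind {kind!r}")


def save_config(cfg, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
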