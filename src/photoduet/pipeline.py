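"""End-to-end orchestration: simulate -> preprocess -> quantify -> lag
correlation -> dose/behaviour statistics, with manifest bookkeeping.

Everything here is a thin composition of the library modules; each stage's
row counts (trials in/out, dropped, censored) are recorded in the run
manifest so trial filters remain auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import AnalysisConfig, SimConfig
from .events import filter_trials, quantify_trials
from .exceptions import ConfigError, StageError
from .lagcorr import lag_scan_iti, lag_scan_trials
from .preprocess import align_trials, preprocess_sensor
from .session import SessionRecord
from .stats import auc_latency_correlation, dose_response_table, press_latency
from .synth import generate_session

logger = logging.getLogger(__name__)


def simulate_cohort(base: SimConfig, n_subjects: int = 5,
                    doses: list[str] | None = None, seed: int = 0
                    ) -> list[tuple[SessionRecord, pd.DataFrame]]:
    """Simulate one session per subject x dose.

    Subjects get a mild random scaling of all kernel amplitudes (between-
    subject variability) and a derived seed; within a subject the same seed
    is reused across doses so dose contrasts are paired, as in a
    repeated-measures design.
    """
    doses = list(doses) if doses is not None else list(base.dose_effect)
    rng = np.random.default_rng(seed)
    out = []
    for s in range(n_subjects):
        scale = float(np.clip(rng.normal(1.0, 0.1), 0.5, 2.0))
        subj_seed = int(rng.integers(0, 2**31 - 10))
        cfg = base.replace(
            da_peak_amp_pct=base.da_peak_amp_pct * scale,
            ach_dip_amp_pct=base.ach_dip_amp_pct * scale,
            ach_rebound_amp_pct=base.ach_rebound_amp_pct * scale,
            meta_subject=f"m{s + 1:02d}")
        for j, dose in enumerate(doses):
            out.append(generate_session(cfg.replace(dose=dose, seed=subj_seed + j)))
    return out


def trial_latencies(record: SessionRecord) -> pd.DataFrame:
    """Per-trial press latency computed from the session's event streams."""
    ext = record.event_times("lever_extension")
    press = record.event_times("lever_press")
    rows = []
    for k, t_ev in enumerate(ext):
        nxt = ext[k + 1] if k + 1 < ext.size else np.inf
        lat = press_latency(t_ev, press[press >= t_ev], nxt)
        rows.append({"trial": k, "event_time_s": t_ev, "latency_s": lat,
                     "completed": np.isfinite(lat)})
    return pd.DataFrame(rows)


def analyze_session(record: SessionRecord, config: AnalysisConfig,
                    event_label: str = "lever_extension") -> dict:
    """Full single-session analysis.

    Returns a dict with the per-trial metrics table (ACh dip metrics joined
    with DA peak metrics and press latency), the trial and ITI lag-correlation
    results, and per-sensor trial matrices.
    """
    lat = trial_latencies(record)
    events = record.event_times(event_label)

    matrices, traces = {}, {}
    for sensor in ("ACh", "DA"):
        traces[sensor] = preprocess_sensor(record, sensor, config)
        matrices[sensor] = align_trials(traces[sensor], events, config,
                                        trial_meta=lat)

    ach_metrics = quantify_trials(matrices["ACh"], config, sensor_role="ach")
    da_metrics = quantify_trials(matrices["DA"], config, sensor_role="da")
    metrics = ach_metrics.merge(
        da_metrics[["trial", "amplitude_pct", "t_max_s", "auc", "qualified"]],
        on="trial", suffixes=("", "_da")).rename(columns={
            "amplitude_pct_da": "da_amplitude_pct", "auc": "da_auc",
            "qualified_da": "da_qualified"})
    for key in ("subject", "dose", "genotype"):
        metrics[key] = record.meta.get(key, "")

    lag_trial = lag_scan_trials(matrices["DA"], matrices["ACh"], config)
    lag_iti = lag_scan_iti(traces["DA"], traces["ACh"], events, config)
    return {"metrics": metrics, "lag_trial": lag_trial, "lag_iti": lag_iti,
            "trials": matrices, "traces": traces,
            "n_dropped": matrices["ACh"].n_dropped}


def _lag_row(record: SessionRecord, res, segment: str) -> dict:
    return {"subject": record.meta.get("subject", ""),
            "dose": record.meta.get("dose", ""),
            "genotype": record.meta.get("genotype", ""), "segment": segment,
            "neg_r": res.neg_peak.r if res.neg_peak else np.nan,
            "neg_lag_s": res.neg_peak.lag_s if res.neg_peak else np.nan,
            "neg_var_pct": res.neg_peak.variance_explained_pct if res.neg_peak else np.nan,
            "pos_r": res.pos_peak.r if res.pos_peak else np.nan,
            "pos_lag_s": res.pos_peak.lag_s if res.pos_peak else np.nan,
            "pos_var_pct": res.pos_peak.variance_explained_pct if res.pos_peak else np.nan,
            "n_trials": res.n_trials}


def run_pipeline(sessions: list[tuple[SessionRecord, pd.DataFrame | None]],
                 config: AnalysisConfig, out_dir: str | Path,
                 dose_order: list[str] | None = None) -> dict:
    """Analyse a list of sessions and write the report directory.

    Emits metrics.csv, lagcorr.csv, dose_response.csv, anova.csv,
    correlations.csv, per-condition trial-average trace CSVs, and
    manifest.json.  Returns the manifest dict.
    """
    if not sessions:
        raise ConfigError("no sessions")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    all_metrics, lag_rows, avg_traces = [], [], {}
    counts = {"sessions": len(sessions), "trials_in": 0, "trials_dropped": 0,
              "trials_censored": 0}
    for record, _truth in sessions:
        try:
            res = analyze_session(record, config)
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise StageError("analyze_session",
                             f"session {record.meta.get('subject', '?')}/"
                             f"{record.meta.get('dose', '?')}: {exc}") from exc
        m = res["metrics"]
        counts["trials_in"] += len(m) + res["n_dropped"]
        counts["trials_dropped"] += res["n_dropped"]
        counts["trials_censored"] += int(m["censored"].sum())
        all_metrics.append(m)
        lag_rows.append(_lag_row(record, res["lag_trial"], "trial"))
        lag_rows.append(_lag_row(record, res["lag_iti"], "iti"))
        key = (record.meta.get("dose", ""), record.meta.get("genotype", ""))
        tm = res["trials"]
        entry = avg_traces.setdefault(key, {"rel_time_s": tm["ACh"].rel_time_s,
                                            "ACh": [], "DA": []})
        if tm["ACh"].n_trials:
            entry["ACh"].append(tm["ACh"].values.mean(axis=0))
            entry["DA"].append(tm["DA"].values.mean(axis=0))

    metrics = pd.concat(all_metrics, ignore_index=True)
    metrics.to_csv(out_dir / "metrics.csv", index=False)
    lagcorr = pd.DataFrame(lag_rows)
    lagcorr.to_csv(out_dir / "lagcorr.csv", index=False)

    for (dose, genotype), entry in avg_traces.items():
        if not entry["ACh"]:
            continue
        df = pd.DataFrame({"rel_time_s": entry["rel_time_s"],
                           "ach_dff_pct": np.mean(entry["ACh"], axis=0),
                           "da_dff_pct": np.mean(entry["DA"], axis=0)})
        name = f"avg_trace_{dose}_{genotype}".replace("/", "-") + ".csv"
        df.to_csv(out_dir / name, index=False)

    doses_present = [d for d in (dose_order or metrics["dose"].unique().tolist())
                     if d in set(metrics["dose"])]
    anova_rows, dr_tables = [], []
    if len(doses_present) >= 2 and metrics["subject"].nunique() >= 2:
        for metric in ("duration_s", "neg_auc", "rebound_auc", "total_auc",
                       "amplitude_pct"):
            qualified = metrics[metrics["qualified"]]
            dr = dose_response_table(qualified, metric, doses_present)
            tab = dr.table.reset_index().melt(id_vars="subject", var_name="dose",
                                              value_name=metric)
            tab.insert(0, "metric", metric)
            dr_tables.append(tab.rename(columns={metric: "value"}))
            row = {"metric": metric, "spearman_rho": dr.spearman_rho,
                   "spearman_p": dr.spearman_p}
            if dr.anova is not None:
                a = dr.anova
                row.update(F=a.F, df_effect=a.df_effect, df_error=a.df_error,
                           p=a.p, partial_eta_sq=a.partial_eta_sq,
                           epsilon_gg=a.epsilon_gg, mean_r_repeated=a.mean_r_repeated)
            anova_rows.append(row)
        pd.concat(dr_tables, ignore_index=True).to_csv(
            out_dir / "dose_response.csv", index=False)
        pd.DataFrame(anova_rows).to_csv(out_dir / "anova.csv", index=False)

    corr_rows = []
    pressed = filter_trials(metrics[np.isfinite(metrics["latency_s"])], config)
    for field in ("total_auc", "neg_auc"):
        if len(pressed) >= 4:
            r, p, n = auc_latency_correlation(pressed, field)
            corr_rows.append({"field": field, "r": r, "p": p, "n": n})
    pd.DataFrame(corr_rows).to_csv(out_dir / "correlations.csv", index=False)

    manifest = {
        "version": __version__,
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()).hexdigest(),
        "seeds": sorted({int(r.meta.get("seed", -1)) for r, _ in sessions}),
        "counts": counts,
        "outputs": sorted(p.name for p in out_dir.glob("*.csv")),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
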