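# photoduet

Analysis pipeline for **dual-sensor fiber photometry** of striatal dopamine
(DA, e.g. dLight1.2) and acetylcholine (ACh, e.g. GACh3.0) recorded
simultaneously, each with a 465 nm signal channel and a 405 nm isosbestic
control channel. It is written for experimenters who align neuromodulator
signals to behavioural events (lever extension, CS onset, optogenetic light
pulses) and need reproducible, per-trial quantification of the canonical
DA-peak / ACh-dip motif and of how it changes with drug dose, genotype and
behaviour.

## What it computes

1. **Motion-corrected ΔF/F.** Both wavelengths are decimated by a
   moving-window (block) mean, the isosbestic channel is fit to the signal
   channel by least squares (`F0 = a·F405 + b`), and
   `ΔF/F (%) = (F465 − F0)/F0 × 100`. Shared motion artifacts and slow
   photobleaching cancel in this step.
2. **Event-aligned trial matrices.** 15 s windows ([−5, +10] s) around each
   event, with the mean of the 5 s pre-event baseline subtracted per trial.
3. **ACh dip / DA peak metrics.** Per trial, within the 5 s post-event
   window: extremum amplitude (qualified at ≥ k·SD of the local baseline,
   k = 2 by default), dip duration between zero crossings located by linear
   interpolation, and the AUC decomposition — total (signed), negative
   (between the dip's crossings) and rebound (positive lobe following the
   dip).
4. **Lagged DA–ACh cross-correlation.** Pearson r per trial at every
   integer-sample lag τ ∈ [−3, +3] s (negative τ = ACh lags DA), averaged
   across trials; the negative extremum (the dip trailing the DA peak) and a
   positive extremum at longer lags (the rebound) are reported with variance
   explained `r² × 100`. The same scan runs on 10 s chunks of the inter-trial
   interval. Fisher's z is provided for comparing correlations.
5. **Behaviour and statistics.** Press latencies, the trial filter
   (latency > 2 s), AUC–latency Pearson correlations, Pavlovian anticipatory
   responding (max of quintiles 4/5 minus quintile 1), one-way
   repeated-measures ANOVA with Greenhouse–Geisser ε, and the effect-size /
   power chain: partial η² = F·df₁/(F·df₁ + df₂), Cohen's
   f = √(η²/(1−η²)), and the smallest n reaching a target power for the
   noncentral-F test with λ = f²·n·m·ε/(1−ρ).
6. **Synthetic sessions with ground truth** (`photoduet.synth`): seeded
   dual-sensor recordings with event-locked kernels (DA transient; ACh
   initial peak, dip, rebound), dose-dependent dip shortening and rebound
   enhancement, genotype decoupling, shared motion artifacts,
   photobleaching, spontaneous ITI transients and latency–AUC coupling —
   used by the test suite to verify that the pipeline recovers known
   parameters.

## Worked example

```python
from photoduet import SimConfig, AnalysisConfig, generate_session, analyze_session

sim = SimConfig(sampling_rate_hz=250, n_trials=20, seed=1)
record, truth = generate_session(sim)
res = analyze_session(record, AnalysisConfig())

m = res["metrics"]
q = m[m["qualified"]]
print(f"trials analysed: {len(m)} (dip qualified: {len(q)})")
print(f"ACh dip: amplitude {q['amplitude_pct'].mean():.2f} %, "
      f"duration {q['duration_s'].mean():.2f} s")
print(f"AUC (%.s): neg {q['neg_auc'].mean():.2f}, "
      f"rebound {q['rebound_auc'].mean():.2f}, total {q['total_auc'].mean():.2f}")
neg, pos = res["lag_trial"].neg_peak, res["lag_trial"].pos_peak
print(f"trial lag-corr: r={neg.r:.3f} at {neg.lag_s*1000:.0f} ms "
      f"({neg.variance_explained_pct:.1f}% variance); "
      f"rebound r={pos.r:.3f} at {pos.lag_s:.2f} s")
```

prints

```
trials analysed: 20 (dip qualified: 20)
ACh dip: amplitude -3.01 %, duration 1.04 s
AUC (%.s): neg -1.83, rebound 0.70, total -0.78
trial lag-corr: r=-0.833 at -200 ms (69.3% variance); rebound r=0.356 at -1.56 s
```

The generator placed a −3 % ACh dip of 1.0 s duration whose minimum trails
the DA peak by 180 ms, with a rebound peaking 1.5 s after the DA peak; the
pipeline recovers the amplitude and duration to a few percent and both lags
to within one downsampled sample (40 ms here).

A command-line interface wraps the same steps:

```sh
photoduet simulate --seed 1 --out session_dir
photoduet quantify --in session_dir/session.h5 --out metrics.csv
photoduet run --simulate sim.yaml --subjects 5 --seed 0 --out report/
```

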