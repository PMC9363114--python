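# Methods

This note documents the models, conventions and numerical choices behind
photoduet, what the synthetic-data generator does and does not emulate, and
the known limitations.

## Signal model and preprocessing

Each sensor contributes two raw-fluorescence channels on a common time base:
a 465 nm signal channel carrying activity-dependent fluorescence and a
405 nm isosbestic channel that is activity-independent but shares motion
artifacts and photobleaching. Processing order per sensor:

1. **Downsampling** by a non-overlapping block mean (true decimation,
   default factor 10; trailing partial blocks dropped). The time base is
   decimated identically, each output sample carrying the mean time of its
   block.
2. **Isosbestic regression.** One least-squares fit of the 405 nm trace to
   the 465 nm trace per session (`F0 = a·F405 + b`). A per-trial fit over a
   5 s baseline would be underdetermined and was deliberately avoided. A
   constant 405 trace raises a degenerate-fit error rather than silently
   returning slope 0.
3. **ΔF/F** = (F465 − F0)/F0 × 100, in percent. Any non-positive F0 is an
   error carrying the fit diagnostics.
4. **Trial alignment.** Windows of [−window_pre, +window_post] (default
   [−5, +10] s, i.e. a 15 s window; the asymmetric split leaves room for the
   5 s baseline and the 5 s quantification window plus the rebound tail) are
   cut around each event by nearest-sample alignment; the mean of the
   [−5, 0) s segment is subtracted per trial. Windows that do not fit inside
   the recording are dropped and counted.

Because the fit removes only the *common* component, a shared multiplicative
motion artifact cancels exactly; an additive offset applied to both channels
is absorbed into the intercept but rescales ΔF/F by ~(F0+c)/F0, which the
test suite checks as a shape-preserving scalar.

## Dip / peak quantification

Within (0, auc_window] s after the event (default 5 s):

- **Amplitude** is the extremum of the baseline-subtracted row. A dip
  qualifies when amplitude ≤ −k·SD of the local baseline (k = dip_sd_k,
  default 2; the detection threshold is deliberately a configuration knob —
  1 is a common, more liberal choice — and the default is the conservative
  of the two).
- **Duration** runs from the last zero down-crossing before the minimum to
  the first zero up-crossing after it, crossings located by linear
  interpolation between adjacent samples. A dip that has not returned to
  zero by the window end keeps duration = window length and is flagged
  *censored* rather than excluded, since exclusion would bias dose
  comparisons.
- **AUC decomposition** by trapezoidal integration with the crossing points
  inserted into the grid (exact for piecewise-linear data): *total* is the
  signed integral over the whole window; *negative* the integral between the
  dip's crossings; *rebound* the positive part from the dip's end crossing
  to the next down-crossing or the window end (zero if the dip is censored).
  The initial ACh peak is not reported separately; it is recoverable as
  total minus the other components.
- **Optogenetic onset latency**: first t > 0 at which the signal stays below
  −k·SD for ≥ 50 ms.

Numerical choices: values within an absolute *zero band* (default
1e−3 %ΔF/F) count as zero for crossing detection, so the ~1e−4 % residue the
bleach/regression interaction leaves in ΔF/F cannot push a crossing to the
window edge; the band is far below both photometric noise and any reportable
signal. When a crossing pair starts from an exactly-zero sample (a flat
baseline run, which arises in noise-free data), the true departure point
lies inside that sample interval and is estimated by extrapolating the
adjacent signal segment back to zero, clamped to the interval — snapping to
the zero sample would systematically widen every dip by up to one sample.

## Lagged cross-correlation

Pearson r is computed per trial at every integer-sample lag over ±lag_max
(default 3 s) on the overlapping segment, then averaged across trials —
never on concatenated traces, so between-trial baseline differences cannot
masquerade as correlation. Sign convention: negative lag means the ACh
series is shifted such that its features occur after DA's ("ACh lags DA").
The negative extremum is the global minimum of the mean curve; the positive
extremum is the maximum restricted to lags ≤ −0.5 s (configurable) so the
slow rebound correlation is not shadowed by the shoulder of the trough;
ties break toward the smaller |lag|. Constant segments yield undefined r and
are excluded from the average. ITI correlation uses the same scan on 10 s
chunks of the recording outside every trial window; fixed-length chunking
keeps per-segment sample counts comparable. Reported lags are grid lags
(~10 ms at the default rates); no sub-sample interpolation is attempted.

## Repeated-measures statistics and power

The one-way within-subjects ANOVA uses the standard decomposition
SS_total = SS_conditions + SS_subjects + SS_error, with Greenhouse–Geisser
ε estimated from the doubly-centred sample covariance of the condition
columns (ε = tr(S̃)² / ((m−1)·tr(S̃²)), clipped to [1/(m−1), 1]; ε ≡ 1 for
m = 2) multiplying both degrees of freedom. Effect sizes follow
partial η² = F·df_effect/(F·df_effect + df_error) computed on the corrected
dfs, and Cohen's f = √(η²/(1−η²)). Missing cells raise an error pointing to
mixed-model tools; unbalanced designs are out of scope.

The sample-size search uses the within-factors noncentral-F convention:
λ = f²·n·m·ε/(1−ρ), df₁ = (m−1)ε, df₂ = (n−1)(m−1)ε, where m is the number
of repeated measures and ρ the mean correlation among them; the smallest
n ≥ 2 with power ≥ target is returned. Because software packages differ in
their repeated-measures effect-size conventions, ρ and ε are explicit inputs
and the analytic power is cross-checked in the tests against a 50 000-draw
Monte-Carlo noncentral-F simulation (agreement within 0.01).

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes, not
striatal biophysics. Event-locked components are **half-sine bumps**:
compact support makes the configured dip duration exactly the
zero-crossing-to-zero-crossing duration, even symmetry makes configured
peak-to-peak lags exactly the cross-correlation extremum lags, and the
non-zero edge slope keeps crossing estimates stable under sample noise.
Only timing, amplitude and duration of the components are scientifically
constrained; the waveform family is a free modelling choice.

Defaults (per trial, ΔF/F %): DA transient +5 % peaking 0.5 s after lever
extension (width 0.8 s); ACh dip −3 %, 1.0 s duration, minimum 0.18 s after
the DA peak; rebound +1 % peaking 1.5 s after the DA peak, its bump starting
flush at the dip's end crossing (so the positive component immediately
follows the decrease, as in vivo); optional initial ACh peak (default off —
the "no initial peak" phenotype). Trial-to-trial amplitudes jitter with
CV 0.2. ITIs are exponential (scale 40 s) truncated to [20, 80] s. Dose
effects multiply dip duration (downward), rebound amplitude (upward) and DA
amplitude (upward), emulating a D2R-antagonist series; the knockout genotype
halves the DA-coupled dip/rebound components; "sensor blocked" zeroes all
event-locked kernels; optogenetic modes replace the ACh response with a
0.5 s square dip ramping back over 1 s (short) or 3 s (long, plus a rebound
overshoot). Press latency is Normal(base + slope·total-AUC, 0.5 s) floored
at 0.1 s, giving the positive AUC–latency coupling. Spontaneous coupled
DA–ACh transients (half amplitude, 0.1 Hz) occur away from trial windows so
the ITI correlation exists but is weaker than the cue-evoked one.

Nuisance terms: a single multiplicative bleaching exponential (τ = 2000 s),
shared motion bumps of ~1 % with random sign (identical fractional
contribution to 405 and 465 — the geometry that makes isosbestic correction
exact), and white per-sample noise (0.3 % of baseline at the raw rate; no
amplitude scale for motion or noise is published, so these are free,
realistic choices fixed once). What the generator does **not** emulate:
sensor kinetics and nonlinearity, correlated (1/f) noise, hemodynamic
artifacts, multi-event kernel overlap within a trial, and session-scale
non-stationarity. Passing recovery tests therefore demonstrates the
pipeline's correctness on data satisfying its assumptions, not robustness to
every artifact of real recordings.

## Test problem sizes

Recovery suites use 20 seeded cohorts at 250 Hz raw (25 Hz after
decimation), 8–12 trials per session, 4 subjects × 6 doses for the
dose-effect suite, and 60-trial sessions at 125 Hz for the behavioural
coupling checks — small enough to run the whole suite in well under a
minute per suite while leaving the statistical margins wide (ordering checks
pass in ≥ 18/20 seeds by design margin, not by tuning).

## Known limitations

- The lag grid is the downsampled sample grid; reported lags are quantized
  (±20 ms at 25 Hz).
- Duration estimates carry a small inward noise bias (~tens of ms at default
  noise) because the first threshold-satisfying crossing is taken.
- The ITI-vs-trial correlation ratio depends nonlinearly on SNR, so only its
  ordering (ITI weaker), not its value, is a stable property of the
  generator's coupling ratio.
- Two-way mixed designs, post-hoc families and mixed-effects models for
  missing data are intentionally delegated to general statistics packages.
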