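"""Behavioural metrics, AUC-latency correlations, one-way repeated-measures
ANOVA with Greenhouse-Geisser correction, and the effect-size / power chain.

The power chain mirrors the within-factors repeated-measures ANOVA
convention: partial eta^2 = F*df_effect / (F*df_effect + df_error), Cohen's
f = sqrt(eta^2 / (1 - eta^2)), and the noncentral-F power calculation with
noncentrality lambda = f^2 * n * m * epsilon / (1 - rho), numerator df
(m-1)*epsilon and denominator df (n-1)*(m-1)*epsilon, where m is the number
of repeated measures, rho the mean correlation among them and epsilon the
non-sphericity correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import AnalysisConfig
from .exceptions import ConfigError, PhotoduetError


# ---------------------------------------------------------------- behaviour

def press_latency(extension_time: float, press_times: np.ndarray,
                  next_extension_time: float = np.inf) -> float:
    """Latency from lever extension to the first press before the next
    extension; +inf if the trial was never completed."""
    press_times = np.asarray(press_times, dtype=float)
    if np.any(press_times < extension_time):
        raise PhotoduetError("lever press precedes lever extension")
    valid = press_times[(press_times >= extension_time)
                        & (press_times < next_extension_time)]
    if valid.size == 0:
        return float("inf")
    return float(valid.min() - extension_time)


def anticipatory_index(head_entry_times: np.ndarray, cs_on: float,
                       cs_duration: float, n_quintiles: int = 5) -> int:
    """Anticipatory responding during a CS presentation.

    Head entries are binned into quintiles of the CS window; the index is the
    larger of the last two quintile counts minus the first quintile count.
    """
    if cs_duration <= 0:
        raise ConfigError("cs_duration must be positive")
    times = np.asarray(head_entry_times, dtype=float)
    rel = (times - cs_on) / cs_duration
    rel = rel[(rel >= 0) & (rel < 1)]
    counts, _ = np.histogram(rel, bins=n_quintiles, range=(0.0, 1.0))
    return int(max(counts[-2], counts[-1]) - counts[0])


def auc_latency_correlation(metrics: pd.DataFrame, field: str = "total_auc",
                            latency_col: str = "latency_s"
                            ) -> tuple[float, float, int]:
    """Pearson correlation between a per-trial AUC field and press latency.

    Expects a table already restricted to analysable trials (finite latency,
    latency filter applied upstream).  Returns (r, two-sided p, n).
    """
    sub = metrics[[field, latency_col]].replace([np.inf, -np.inf], np.nan).dropna()
    n = len(sub)
    if n < 4:
        raise ConfigError(f"need at least 4 trials for a correlation, got {n}")
    r, p = sps.pearsonr(sub[field], sub[latency_col])
    return float(r), float(p), n


# ------------------------------------------------------------------- ANOVA

@dataclass
class AnovaResult:
    """One-way repeated-measures ANOVA with Greenhouse-Geisser correction."""

    F: float
    df_effect: float        # GG-corrected
    df_error: float         # GG-corrected
    p: float
    partial_eta_sq: float
    epsilon_gg: float
    mean_r_repeated: float
    n_subjects: int
    n_conditions: int

    def summary(self) -> str:
        return (f"RM ANOVA: F({self.df_effect:.3f}, {self.df_error:.3f}) = "
                f"{self.F:.3f}, p = {self.p:.4f}; partial eta^2 = "
                f"{self.partial_eta_sq:.3f}, GG epsilon = {self.epsilon_gg:.4f}, "
                f"mean r among measures = {self.mean_r_repeated:.3f} "
                f"(n = {self.n_subjects} subjects, m = {self.n_conditions})")


def greenhouse_geisser_epsilon(data: np.ndarray) -> float:
    """GG non-sphericity epsilon from the sample covariance of the condition
    columns, clipped to its theoretical range [1/(m-1), 1]."""
    data = np.asarray(data, dtype=float)
    m = data.shape[1]
    if m == 2:
        return 1.0
    s = np.cov(data, rowvar=False)
    h = np.eye(m) - np.ones((m, m)) / m
    sd = h @ s @ h
    num = np.trace(sd) ** 2
    den = (m - 1) * np.trace(sd @ sd)
    if den <= 0:
        return 1.0
    return float(np.clip(num / den, 1.0 / (m - 1), 1.0))


def rm_anova_oneway(data) -> AnovaResult:
    """One-way within-subjects ANOVA on a complete subjects x conditions table.

    Sums of squares by the standard within-subjects decomposition; the GG
    epsilon multiplies both degrees of freedom before the p-value and the
    partial eta^2 are computed.
    """
    if isinstance(data, pd.DataFrame):
        data = data.to_numpy(dtype=float)
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ConfigError("data must be a 2-D subjects x conditions table")
    if np.any(~np.isfinite(data)):
        raise ConfigError("missing cells: complete cases required "
                          "(use external mixed-model tools for unbalanced data)")
    n, m = data.shape
    if n < 2 or m < 2:
        raise ConfigError("need at least 2 subjects and 2 conditions")

    grand = data.mean()
    cond_means = data.mean(axis=0)
    subj_means = data.mean(axis=1)
    ss_cond = n * float(((cond_means - grand) ** 2).sum())
    ss_subj = m * float(((subj_means - grand) ** 2).sum())
    ss_total = float(((data - grand) ** 2).sum())
    ss_err = ss_total - ss_cond - ss_subj

    df1, df2 = m - 1, (n - 1) * (m - 1)
    ms_cond = ss_cond / df1
    ms_err = ss_err / df2
    f_stat = ms_cond / ms_err if ms_err > 0 else 0.0

    eps = greenhouse_geisser_epsilon(data)
    df1_c, df2_c = df1 * eps, df2 * eps
    p = float(sps.f.sf(f_stat, df1_c, df2_c)) if f_stat > 0 else 1.0
    eta2 = partial_eta_sq(f_stat, df1_c, df2_c)

    with np.errstate(invalid="ignore", divide="ignore"):
        cm = np.corrcoef(data, rowvar=False)
    off = cm[~np.eye(m, dtype=bool)]
    off = off[np.isfinite(off)]
    mean_r = float(off.mean()) if off.size else np.nan

    return AnovaResult(F=float(f_stat), df_effect=df1_c, df_error=df2_c, p=p,
                       partial_eta_sq=eta2, epsilon_gg=eps,
                       mean_r_repeated=mean_r, n_subjects=n, n_conditions=m)


# --------------------------------------------------------- effect size / power

def partial_eta_sq(F: float, df_effect: float, df_error: float) -> float:
    """partial eta^2 = F*df_effect / (F*df_effect + df_error)."""
    if F < 0 or df_effect <= 0 or df_error <= 0:
        raise ConfigError("require F >= 0 and positive degrees of freedom")
    return float(F * df_effect / (F * df_effect + df_error))


def cohens_f(eta2: float) -> float:
    """Cohen's f = sqrt(eta^2 / (1 - eta^2))."""
    if not 0.0 <= eta2 <= 1.0:
        raise ConfigError("eta2 must lie in [0, 1]")
    if eta2 == 1.0:
        raise PhotoduetError("eta2 = 1 gives an infinite effect size f")
    return float(np.sqrt(eta2 / (1.0 - eta2)))


@dataclass
class PowerSpec:
    """Inputs and result of the repeated-measures sample-size calculation."""

    f: float
    alpha: float = 0.05
    power_target: float = 0.8
    m: int = 2
    rho: float = 0.0
    epsilon: float = 1.0
    n_required: int | None = None

    def summary(self) -> str:
        return (f"RM within-factors power: f = {self.f:g}, alpha = {self.alpha:g}, "
                f"target power = {self.power_target:g}, m = {self.m}, "
                f"rho = {self.rho:g}, epsilon = {self.epsilon:g} "
                f"-> n = {self.n_required}")


def rm_power(f: float, n: int, m: int, alpha: float, rho: float,
             epsilon: float) -> float:
    """Power of the repeated-measures within-factors F test at sample size n."""
    lam = f * f * n * m * epsilon / (1.0 - rho)
    df1 = (m - 1) * epsilon
    df2 = (n - 1) * (m - 1) * epsilon
    f_crit = sps.f.isf(alpha, df1, df2)
    return float(sps.ncf.sf(f_crit, df1, df2, lam))


def rm_sample_size(spec: PowerSpec, n_max: int = 10**6) -> int:
    """Smallest n >= 2 whose analytic power reaches the target."""
    if spec.f <= 0:
        raise ConfigError("effect size f must be positive")
    if not (0 < spec.alpha < 1 and 0 < spec.power_target < 1):
        raise ConfigError("alpha and power_target must lie in (0, 1)")
    if spec.m < 2:
        raise ConfigError("need m >= 2 repeated measures")
    if not (-1 < spec.rho < 1):
        raise ConfigError("rho must lie in (-1, 1)")
    if not (1.0 / (spec.m - 1) <= spec.epsilon <= 1.0 + 1e-12):
        raise ConfigError("epsilon must lie in (1/(m-1), 1]")
    n = 2
    while n <= n_max:
        if rm_power(spec.f, n, spec.m, spec.alpha, spec.rho, spec.epsilon) \
                >= spec.power_target:
            spec.n_required = n
            return n
        n += 1
    raise PhotoduetError(f"target power not reachable at n = {n_max}")


# ------------------------------------------------------------- dose response

@dataclass
class DoseResponse:
    table: pd.DataFrame             # subjects x doses means of the metric
    metric: str
    spearman_rho: float             # trend of the metric vs dose rank
    spearman_p: float
    anova: AnovaResult | None       # None when < 2 subjects


def dose_response_table(metrics: pd.DataFrame, metric: str,
                        dose_order: list[str],
                        subject_col: str = "subject",
                        dose_col: str = "dose") -> DoseResponse:
    """Subject x dose summary of a per-trial metric, with RM ANOVA and trend.

    Per-subject means per dose feed the one-way RM ANOVA (complete-case
    subjects only); the Spearman trend correlates the subject-level means with
    the dose rank in ``dose_order``.
    """
    if len(dose_order) < 2:
        raise ConfigError("need at least 2 doses for a dose-response analysis")
    sub = metrics[metrics[dose_col].isin(dose_order)]
    pivot = (sub.groupby([subject_col, dose_col], sort=False)[metric]
             .mean().unstack(dose_col).reindex(columns=dose_order))
    complete = pivot.dropna()
    if len(complete) < len(pivot):
        dropped = sorted(set(pivot.index) - set(complete.index))
        import logging
        logging.getLogger(__name__).info(
            "dose_response_table: dropped incomplete subjects %s", dropped)
    ranks = np.arange(len(dose_order))
    long = complete.melt(ignore_index=False, var_name=dose_col, value_name=metric)
    dose_rank = long[dose_col].map(dict(zip(dose_order, ranks)))
    rho, p = sps.spearmanr(dose_rank, long[metric])
    anova = rm_anova_oneway(complete) if len(complete) >= 2 else None
    return DoseResponse(table=complete, metric=metric, spearman_rho=float(rho),
                        spearman_p=float(p), anova=anova)
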