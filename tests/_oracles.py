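"""Independent brute-force oracles used by the test suite.

These re-derive dip duration, the AUC decomposition and the RM-ANOVA sums of
squares from first principles (dense grids, explicit loops), independently of
the package implementation.
"""

import numpy as np


def dense_dip_oracle(rel_time, row, auc_window_s, oversample=1000,
                     zero_band=0.0):
    """Dip duration + (total, neg, rebound) AUC on a densely resampled grid.

    ``zero_band`` mirrors the analysis convention that values within a small
    absolute band around zero count as zero for crossing detection.
    """
    mask = (rel_time >= 0) & (rel_time <= auc_window_s + 1e-12)
    t, v = rel_time[mask], row[mask]
    tf = np.linspace(t[0], t[-1], (t.size - 1) * oversample + 1)
    vf = np.interp(tf, t, v)
    wf = np.where(np.abs(vf) <= zero_band, 0.0, vf)

    total = np.trapezoid(vf, tf)
    pos = tf > 0
    i_min = np.argmin(np.where(pos, vf, np.inf))
    if vf[i_min] >= -zero_band:
        return dict(amplitude=float(vf[i_min]), duration=0.0, total=float(total),
                    neg=0.0, rebound=0.0, censored=False)

    i = i_min
    while i > 0 and wf[i - 1] < 0:
        i -= 1
    pre = tf[i]
    j = i_min
    censored = True
    while j < wf.size - 1:
        if wf[j + 1] >= 0:
            j += 1
            censored = False
            break
        j += 1
    post = tf[j] if not censored else tf[-1]
    neg_mask = (tf >= pre) & (tf <= post)
    neg = np.trapezoid(np.minimum(vf[neg_mask], 0.0), tf[neg_mask])

    rebound = 0.0
    if not censored:
        k = j
        while k < wf.size - 1 and not (wf[k] > 0 >= wf[k + 1]):
            k += 1
        reb_end = tf[k + 1] if k < wf.size - 1 else tf[-1]
        reb_mask = (tf >= post) & (tf <= reb_end)
        rebound = np.trapezoid(np.maximum(vf[reb_mask], 0.0), tf[reb_mask])

    return dict(amplitude=float(vf[i_min]), duration=float(post - pre),
                total=float(total), neg=float(neg), rebound=float(rebound),
                censored=censored)


def rm_anova_ss_oracle(data):
    """Within-subjects sums of squares by explicit cell loops."""
    data = np.asarray(data, dtype=float)
    n, m = data.shape
    grand = data.sum() / (n * m)
    ss_cond = ss_subj = ss_total = 0.0
    for j in range(m):
        cm = data[:, j].sum() / n
        ss_cond += n * (cm - grand) ** 2
    for i in range(n):
        sm = data[i].sum() / m
        ss_subj += m * (sm - grand) ** 2
    for i in range(n):
        for j in range(m):
            ss_total += (data[i, j] - grand) ** 2
    ss_err = ss_total - ss_cond - ss_subj
    df1, df2 = m - 1, (n - 1) * (m - 1)
    f_stat = (ss_cond / df1) / (ss_err / df2)
    return dict(ss_cond=ss_cond, ss_subj=ss_subj, ss_err=ss_err,
                ss_total=ss_total, F=f_stat)


def mc_rm_power_oracle(f, n, m, alpha, rho, epsilon, n_draws=50_000, seed=0):
    """Monte-Carlo power: draw noncentral F statistics and count rejections."""
    from scipy import stats
    lam = f * f * n * m * epsilon / (1.0 - rho)
    df1 = (m - 1) * epsilon
    df2 = (n - 1) * (m - 1) * epsilon
    rng = np.random.default_rng(seed)
    num = rng.noncentral_chisquare(df1, lam, size=n_draws) / df1
    den = rng.chisquare(df2, size=n_draws) / df2
    f_crit = stats.f.isf(alpha, df1, df2)
    return float(np.mean(num / den > f_crit))


def random_piecewise_linear_rows(rel_time, n_rows, seed, knot_every_s=0.4,
                                 amp=2.0):
    """Random piecewise-linear rows on the trial grid, zero in the baseline."""
    rng = np.random.default_rng(seed)
    t0, t1 = rel_time[0], rel_time[-1]
    rows = []
    for _ in range(n_rows):
        knots_t = np.arange(0.0, t1 + knot_every_s, knot_every_s)
        knots_v = rng.uniform(-amp, amp, size=knots_t.size)
        knots_v[0] = 0.0
        row = np.interp(rel_time, knots_t, knots_v, left=0.0, right=knots_v[-1])
        row[rel_time < 0] = 0.0
        rows.append(row)
    return np.vstack(rows)
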