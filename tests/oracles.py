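"""Independent reference implementations used to check the package.

Everything here is deliberately naive — per-sample loops, exhaustive
enumeration, direct textbook formulas — and shares no code with the
package's own implementations.
"""

from __future__ import annotations

import itertools

import numpy as np
import scipy.stats as st


def brute_force_detect(speed, onset_thr, offset_thr):
    """Exhaustive per-sample scan for dual-threshold saccade boundaries.

    For every sample at or above the onset threshold (not already claimed),
    walk left and right while samples stay at or above the offset
    threshold; the event spans one sample beyond the supra-threshold run on
    each side (clipped at the trace ends).  Returns (onset_idx, offset_idx)
    pairs, unmerged and unfiltered.
    """
    n = len(speed)
    claimed = np.zeros(n, dtype=bool)
    out = []
    for i in range(n):
        if speed[i] < onset_thr or claimed[i]:
            continue
        lo = i
        while lo > 0 and speed[lo - 1] >= offset_thr:
            lo -= 1
        hi = i
        while hi < n - 1 and speed[hi + 1] >= offset_thr:
            hi += 1
        claimed[lo:hi + 1] = True
        out.append((max(lo - 1, 0), min(hi + 1, n - 1)))
    return out


def signed_rank_exact(diffs):
    """(V, two-sided exact p) by enumerating all 2^n sign assignments."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    ranks = st.rankdata(np.abs(d))
    v = ranks[d > 0].sum()
    dist = np.array([
        sum(r for s, r in zip(signs, ranks) if s)
        for signs in itertools.product([0, 1], repeat=len(d))
    ])
    p = min(1.0, 2 * min((dist <= v).mean(), (dist >= v).mean()))
    return float(v), float(p)


def rank_sum_exact(a, b):
    """(W, two-sided exact p) by enumerating all group assignments."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    ranks = st.rankdata(pooled)
    n1 = len(a)
    w = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    dist = np.array([
        ranks[list(idx)].sum() - n1 * (n1 + 1) / 2
        for idx in itertools.combinations(range(len(pooled)), n1)
    ])
    p = min(1.0, 2 * min((dist <= w).mean(), (dist >= w).mean()))
    return float(w), float(p)


def paired_t_formula(a, b):
    """(t, df, two-sided p) from the textbook paired-t formula."""
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    n = len(d)
    t = d.mean() / (d.std(ddof=1) / np.sqrt(n))
    return t, n - 1, 2 * st.t.sf(abs(t), n - 1)


def welch_formula(a, b):
    """(t, df, two-sided p) from the Welch-Satterthwaite formulas."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va ** 2 / (len(a) - 1) + vb ** 2 / (len(b) - 1))
    return t, df, 2 * st.t.sf(abs(t), df)


def chi2_formula(table):
    """(chi2, df) summing (O-E)^2/E over all cells."""
    table = np.asarray(table, dtype=float)
    total = table.sum()
    chi2 = 0.0
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            e = table[i].sum() * table[:, j].sum() / total
            chi2 += (table[i, j] - e) ** 2 / e
    return chi2, (table.shape[0] - 1) * (table.shape[1] - 1)


def levene_formula(a, b):
    """(F, p) as a one-way ANOVA on absolute deviations from group means."""
    a = np.abs(np.asarray(a, dtype=float) - np.mean(a))
    b = np.abs(np.asarray(b, dtype=float) - np.mean(b))
    n1, n2 = len(a), len(b)
    grand = np.concatenate([a, b]).mean()
    ss_between = n1 * (a.mean() - grand) ** 2 + n2 * (b.mean() - grand) ** 2
    ss_within = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
    f = (ss_between / 1) / (ss_within / (n1 + n2 - 2))
    return f, st.f.sf(f, 1, n1 + n2 - 2)


def mixed_anova_ss(data, dv, within, subject, between):
    """Mixed-design ANOVA F ratios from the sums-of-squares decomposition.

    Balanced within factor (every subject at every level); groups may be
    unbalanced.  Returns {source: (F, df1, df2)}.
    """
    wide = data.pivot_table(index=subject, columns=within, values=dv)
    groups = data.drop_duplicates(subject).set_index(subject)[between]
    groups = groups.reindex(wide.index)
    y = wide.to_numpy()
    n_subj, k = y.shape
    g_labels = groups.to_numpy()
    g_names = sorted(set(g_labels))
    g = len(g_names)
    grand = y.mean()

    subj_means = y.mean(axis=1)
    ss_between_subj = k * ((subj_means - grand) ** 2).sum()
    ss_group = sum(
        k * (g_labels == gn).sum() * (subj_means[g_labels == gn].mean() - grand) ** 2
        for gn in g_names)
    ss_subj_within = ss_between_subj - ss_group

    task_means = y.mean(axis=0)
    ss_task = n_subj * ((task_means - grand) ** 2).sum()
    ss_cells = 0.0
    for gn in g_names:
        sel = g_labels == gn
        ng = sel.sum()
        cell = y[sel].mean(axis=0)
        gm = subj_means[sel].mean()
        ss_cells += ng * ((cell - gm - task_means + grand) ** 2).sum()
    ss_within_subj = ((y - subj_means[:, None]) ** 2).sum()
    ss_error = ss_within_subj - ss_task - ss_cells

    df_group, df_subj = g - 1, n_subj - g
    df_task, df_int = k - 1, (g - 1) * (k - 1)
    df_err = (n_subj - g) * (k - 1)
    return {
        "group": (ss_group / df_group / (ss_subj_within / df_subj), df_group, df_subj),
        "task": (ss_task / df_task / (ss_error / df_err), df_task, df_err),
        "interaction": (ss_cells / df_int / (ss_error / df_err), df_int, df_err),
    }


def monte_carlo_paired_power(d, n, alpha, n_reps, seed):
    """Rejection rate of the two-sided paired t over simulated samples."""
    rng = np.random.default_rng(seed)
    diffs = rng.normal(d, 1.0, size=(n_reps, n))
    t = diffs.mean(axis=1) / (diffs.std(axis=1, ddof=1) / np.sqrt(n))
    crit = st.t.ppf(1 - alpha / 2, n - 1)
    return float((np.abs(t) > crit).mean())
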