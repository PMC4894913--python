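"""Independent brute-force oracles for the statistical tests.

Every statistic here is computed directly from definitional sums of squares
and means, with no shared code with the package implementation.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats as sps


def t_one_sample_oracle(values, null):
    v = np.asarray(values, dtype=float)
    n = len(v)
    t = (v.mean() - null) / (v.std(ddof=1) / math.sqrt(n))
    return t, n - 1, 2 * sps.t.sf(abs(t), n - 1)


def anova_oracle(groups: dict):
    """One-way fixed-effects ANOVA from definitional sums of squares."""
    all_vals = np.concatenate([np.asarray(v, dtype=float) for v in groups.values()])
    grand = all_vals.mean()
    ssb = sum(len(v) * (np.mean(v) - grand) ** 2 for v in groups.values())
    ssw = sum(float(np.sum((np.asarray(v) - np.mean(v)) ** 2)) for v in groups.values())
    k = len(groups)
    n = len(all_vals)
    f = (ssb / (k - 1)) / (ssw / (n - k))
    return f, (k - 1, n - k), sps.f.sf(f, k - 1, n - k)


def lsd_oracle(groups: dict, a, b):
    """Pooled-MSE pairwise t (Fisher's LSD) from definitions."""
    ssw = sum(float(np.sum((np.asarray(v) - np.mean(v)) ** 2)) for v in groups.values())
    n = sum(len(v) for v in groups.values())
    df = n - len(groups)
    mse = ssw / df
    va, vb = np.asarray(groups[a], float), np.asarray(groups[b], float)
    t = (va.mean() - vb.mean()) / math.sqrt(mse * (1 / len(va) + 1 / len(vb)))
    return t, df, 2 * sps.t.sf(abs(t), df)


def mixed_anova_oracle(values: dict):
    """Balanced split-plot ANOVA with a 2-level within factor.

    ``values`` maps group name -> (n_subjects, 2) array (columns = time
    levels).  Returns {effect: (F, (df1, df2), p)} from definitional sums of
    squares: group is tested against subjects-within-group, time and the
    interaction against the within-subject residual.
    """
    groups = {g: np.asarray(v, dtype=float) for g, v in values.items()}
    k = len(groups)
    m = 2
    n_per = {g: v.shape[0] for g, v in groups.items()}
    n_subj = sum(n_per.values())
    all_vals = np.concatenate([v.ravel() for v in groups.values()])
    grand = all_vals.mean()

    ss_group = sum(m * n_per[g] * (v.mean() - grand) ** 2 for g, v in groups.items())
    ss_subj = sum(
        m * float(np.sum((v.mean(axis=1) - v.mean()) ** 2)) for v in groups.values()
    )
    time_means = np.array(
        [sum(v[:, t].sum() for v in groups.values()) / n_subj for t in range(m)]
    )
    ss_time = n_subj * float(np.sum((time_means - grand) ** 2))
    ss_inter = 0.0
    for g, v in groups.items():
        for t in range(m):
            cell = v[:, t].mean()
            ss_inter += n_per[g] * (cell - v.mean() - time_means[t] + grand) ** 2
    ss_err = 0.0
    for g, v in groups.items():
        subj_mean = v.mean(axis=1, keepdims=True)
        cell_mean = v.mean(axis=0, keepdims=True)
        ss_err += float(np.sum((v - subj_mean - cell_mean + v.mean()) ** 2))

    df_group, df_subj = k - 1, n_subj - k
    df_time, df_inter, df_err = m - 1, (k - 1) * (m - 1), (n_subj - k) * (m - 1)
    f_group = (ss_group / df_group) / (ss_subj / df_subj)
    f_time = (ss_time / df_time) / (ss_err / df_err)
    f_inter = (ss_inter / df_inter) / (ss_err / df_err)
    return {
        "group": (f_group, (df_group, df_subj), sps.f.sf(f_group, df_group, df_subj)),
        "time": (f_time, (df_time, df_err), sps.f.sf(f_time, df_time, df_err)),
        "interaction": (f_inter, (df_inter, df_err), sps.f.sf(f_inter, df_inter, df_err)),
    }
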