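"""Inferential battery: t tests, one-way ANOVA, Fisher's LSD, mixed RM-ANOVA.

Thin, uniformly-typed wrappers so every test in the pipeline reports the
same ``StatResult`` (statistic, dfs, two-sided p).  The alpha level used
throughout the pipeline reports is 0.05.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

ALPHA = 0.05


@dataclass(frozen=True)
class StatResult:
    effect: str
    statistic: float
    df: tuple[int, ...]
    p_value: float
    note: str = ""

    def __post_init__(self) -> None:
        if not (math.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value out of range: {self.p_value}")


def one_sample_t(values, null_value: float = 1.0, effect: str = "one_sample_t") -> StatResult:
    """Two-sided one-sample t test of the mean against ``null_value``."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if len(v) < 2:
        raise ValueError("one_sample_t needs at least 2 values")
    if np.ptp(v) == 0.0:
        if v[0] == null_value:
            return StatResult(effect, 0.0, (len(v) - 1,), 1.0, note="degenerate: zero variance")
        return StatResult(effect, math.nan, (len(v) - 1,), math.nan, note="degenerate: zero variance")
    t, p = sps.ttest_1samp(v, null_value)
    return StatResult(effect, float(t), (len(v) - 1,), float(p))


def paired_t(a, b, effect: str = "paired_t") -> StatResult:
    """Two-sided paired t test (t test on within-pair differences vs 0)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"paired samples differ in length: {a.shape} vs {b.shape}")
    if len(a) < 2:
        raise ValueError("paired_t needs at least 2 pairs")
    d = a - b
    if np.ptp(d) == 0.0:
        if d[0] == 0.0:
            return StatResult(effect, 0.0, (len(a) - 1,), 1.0, note="degenerate: zero difference variance")
        return StatResult(effect, math.nan, (len(a) - 1,), math.nan, note="degenerate: zero difference variance")
    t, p = sps.ttest_rel(a, b)
    return StatResult(effect, float(t), (len(a) - 1,), float(p))


def _validate_groups(groups: dict) -> dict:
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    clean = {}
    for name, vals in groups.items():
        v = np.asarray(vals, dtype=float)
        v = v[~np.isnan(v)]
        if len(v) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 usable values")
        clean[name] = v
    return clean


def one_way_anova(groups: dict, effect: str = "one_way_anova") -> StatResult:
    """Fixed-effects one-way ANOVA; df = (k-1, N-k)."""
    clean = _validate_groups(groups)
    k = len(clean)
    n_total = sum(len(v) for v in clean.values())
    f, p = sps.f_oneway(*clean.values())
    return StatResult(effect, float(f), (k - 1, n_total - k), float(p))


def fisher_lsd(
    groups: dict,
    focal_pairs: list[tuple] | None = None,
    welch: bool = False,
) -> list[StatResult]:
    """Fisher's LSD post hoc: pairwise t with pooled MSE, unadjusted p.

    Per LSD convention the p values are not corrected for multiplicity; the
    procedure is protected only by the omnibus F, so a non-significant
    omnibus raises a warning (not an error).  ``welch=True`` switches to
    per-pair Welch t tests instead of the pooled error term.
    """
    clean = _validate_groups(groups)
    omnibus = one_way_anova(clean)
    if omnibus.p_value > ALPHA:
        warnings.warn(
            f"Fisher's LSD after non-significant omnibus F (p={omnibus.p_value:.3f})",
            stacklevel=2,
        )
    names = list(clean)
    if focal_pairs is None:
        focal_pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    for a, b in focal_pairs:
        for name in (a, b):
            if name not in clean:
                raise ValueError(f"pair references unknown group {name!r}")

    n_total = sum(len(v) for v in clean.values())
    k = len(clean)
    df_err = n_total - k
    sse = sum(((v - v.mean()) ** 2).sum() for v in clean.values())
    mse = sse / df_err

    results = []
    for a, b in focal_pairs:
        va, vb = clean[a], clean[b]
        if welch:
            t, p = sps.ttest_ind(va, vb, equal_var=False)
            # Welch-Satterthwaite df, reported rounded down
            sa, sb = va.var(ddof=1) / len(va), vb.var(ddof=1) / len(vb)
            df = (sa + sb) ** 2 / (sa**2 / (len(va) - 1) + sb**2 / (len(vb) - 1))
            results.append(StatResult(f"{a} vs {b}", float(t), (int(df),), float(p), note="welch"))
        else:
            se = math.sqrt(mse * (1.0 / len(va) + 1.0 / len(vb)))
            t = (va.mean() - vb.mean()) / se
            p = 2.0 * sps.t.sf(abs(t), df_err)
            results.append(StatResult(f"{a} vs {b}", float(t), (df_err,), float(p)))
    return results


def mixed_rm_anova(data: pd.DataFrame) -> dict[str, StatResult]:
    """Mixed-design repeated-measures ANOVA: one within factor (2 levels),
    one between factor.

    ``data`` is long-format with columns ``subject``, ``group``, ``time``,
    ``value``.  Subjects missing a time level are dropped with a warning.
    With only two within levels sphericity is not at issue.  Returns results
    keyed ``time``, ``group``, ``interaction``.
    """
    import pingouin as pg

    required = {"subject", "group", "time", "value"}
    missing = required - set(data.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    n_levels = data["time"].nunique()
    counts = data.groupby("subject")["time"].nunique()
    bad = counts[counts < n_levels].index
    if len(bad):
        warnings.warn(
            f"dropping {len(bad)} subject(s) missing a time level: {list(bad)}",
            stacklevel=2,
        )
        data = data[~data["subject"].isin(bad)]
    if data["group"].nunique() < 2:
        raise ValueError("need at least 2 groups")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        table = pg.mixed_anova(
            data=data, dv="value", within="time", subject="subject", between="group"
        )
    out: dict[str, StatResult] = {}
    for _, row in table.iterrows():
        key = {"group": "group", "time": "time", "Interaction": "interaction"}[row["Source"]]
        p = row["p_unc"] if "p_unc" in row else row["p-unc"]
        out[key] = StatResult(
            key, float(row["F"]), (int(row["DF1"]), int(row["DF2"])), float(p)
        )
    return out
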